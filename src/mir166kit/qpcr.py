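"""Relative quantification of stem-loop RT-qPCR data by 2^-ddCt.

Technical replicates are averaged first; dCt = mean Ct(gene) - mean Ct(ref)
within each (treatment, timepoint, biological replicate); ddCt subtracts the
mean control-timepoint dCt; fold = efficiency^-ddCt with efficiency fixed at
2 (perfect doubling, the classic 2^-ddCt assumption).  Means and SDs are
taken over biological replicates, and groups are compared by one-way ANOVA
with Tukey's HSD on log2 folds, summarized as compact letter displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

REFERENCE_GENE = "U6"

CT_COLUMNS = [
    "sample", "treatment", "timepoint_h", "gene",
    "replicate_bio", "replicate_tech", "ct",
]


def delta_ct(
    records: pd.DataFrame, gene: str, reference: str = REFERENCE_GENE
) -> pd.DataFrame:
    """Per-(treatment, timepoint, bio) dCt after tech-replicate averaging.

    Raises if the reference gene is missing from any cell that has target
    measurements, naming the cell.
    """
    df = records
    keys = ["treatment", "timepoint_h", "replicate_bio"]
    tech_means = (
        df[df["gene"].isin([gene, reference])]
        .groupby(keys + ["gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    if gene not in tech_means.columns:
        raise ValueError(f"no Ct records for gene {gene!r}")
    target = tech_means[gene].dropna()
    if reference not in tech_means.columns:
        raise ValueError(f"reference gene {reference!r} absent from table")
    ref = tech_means[reference]
    missing = target.index[ref.reindex(target.index).isna()]
    if len(missing):
        cell = missing[0]
        raise ValueError(
            f"reference {reference!r} missing for cell "
            f"(treatment={cell[0]!r}, timepoint_h={cell[1]}, bio={cell[2]})"
        )
    out = (target - ref.reindex(target.index)).rename("delta_ct").reset_index()
    return out


@dataclass
class FoldChangeResult:
    gene: str
    treatment: str
    timepoint_h: float
    mean_fold: float
    sd_fold: float
    n_bio: int
    letter_group: str = ""
    bio_folds: tuple[float, ...] = ()


def fold_change(
    records: pd.DataFrame,
    gene: str,
    reference: str = REFERENCE_GENE,
    control_timepoint: float = 0.0,
    efficiency: float = 2.0,
) -> list[FoldChangeResult]:
    """Fold changes relative to the control timepoint, per treatment.

    ddCt(bio, t) = dCt(bio, t) - mean dCt(., control); fold = E^-ddCt.
    """
    dct = delta_ct(records, gene, reference)
    results: list[FoldChangeResult] = []
    for treatment, grp in dct.groupby("treatment", sort=False):
        control = grp.loc[grp["timepoint_h"] == control_timepoint, "delta_ct"]
        if control.empty:
            raise ValueError(
                f"control timepoint {control_timepoint} missing for "
                f"treatment {treatment!r}"
            )
        control_mean = control.mean()
        for timepoint, cell in grp.groupby("timepoint_h", sort=True):
            folds = efficiency ** -(cell["delta_ct"] - control_mean)
            folds = folds.to_numpy()
            results.append(
                FoldChangeResult(
                    gene=gene,
                    treatment=str(treatment),
                    timepoint_h=float(timepoint),
                    mean_fold=float(folds.mean()),
                    sd_fold=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                    n_bio=len(folds),
                    bio_folds=tuple(float(x) for x in folds),
                )
            )
    return results


def analytic_log2_sem(noise_sd: float, n_bio: int = 3, n_tech: int = 3) -> float:
    """Standard error of the mean log2 fold estimate under Ct-scale Gaussian
    noise with the given replicate design.

    Each bio dCt carries variance 2*sigma^2/n_tech (target + reference tech
    means); the estimate subtracts the control-timepoint mean dCt, so
    Var(mean log2 fold) = 2 * (2 sigma^2 / n_tech) / n_bio = 4 sigma^2 /
    (n_bio * n_tech).
    """
    return noise_sd * math.sqrt(4.0 / (n_bio * n_tech))


def _tukey_pvalue(mi, mj, ni, nj, mse, df, k):
    if mse == 0:
        return 0.0 if mi != mj else 1.0
    se = math.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
    if se == 0:
        return 0.0 if mi != mj else 1.0
    q = abs(mi - mj) / se
    return float(studentized_range.sf(q, k, df))


def tukey_letters(
    groups: dict[str, np.ndarray | list[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from all-pairs Tukey HSD.

    ``groups`` maps group label -> per-biological-replicate values (log2
    folds).  Groups sharing a letter are not significantly different at
    ``alpha``.  Letters are assigned greedily from the highest group mean.
    """
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    k = len(data)
    n_total = sum(len(v) for v in data.values())
    df = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df
    means = {g: float(v.mean()) for g, v in data.items()}
    sig = {}
    for a, b in combinations(data, 2):
        p = _tukey_pvalue(
            means[a], means[b], len(data[a]), len(data[b]), mse, df, k
        )
        sig[frozenset((a, b))] = p < alpha
    order = sorted(data, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for idx, g in enumerate(order):
        placed = False
        for s in letter_sets:
            if all(not sig[frozenset((g, h))] for h in s):
                s.add(g)
                placed = True
        if not placed:
            fresh = {g}
            for h in order[:idx]:  # keep letters maximal
                if all(not sig[frozenset((h, x))] for x in fresh):
                    fresh.add(h)
            letter_sets.append(fresh)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in data}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def fold_change_table(
    records: pd.DataFrame,
    genes: list[str],
    reference: str = REFERENCE_GENE,
    control_timepoint: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full results table: per gene x treatment x timepoint fold changes
    with Tukey letter groups across timepoints within each treatment."""
    rows = []
    for gene in genes:
        results = fold_change(records, gene, reference, control_timepoint)
        by_treatment: dict[str, list[FoldChangeResult]] = {}
        for r in results:
            by_treatment.setdefault(r.treatment, []).append(r)
        for treatment, rs in by_treatment.items():
            if len(rs) >= 2 and all(r.n_bio >= 2 for r in rs):
                letters = tukey_letters(
                    {
                        f"{r.timepoint_h}": np.log2(r.bio_folds) for r in rs
                    },
                    alpha=alpha,
                )
                for r in rs:
                    r.letter_group = letters[f"{r.timepoint_h}"]
            rows.extend(
                {
                    "gene": r.gene,
                    "treatment": r.treatment,
                    "timepoint_h": r.timepoint_h,
                    "mean_fold": r.mean_fold,
                    "sd_fold": r.sd_fold,
                    "n_bio": r.n_bio,
                    "letters": r.letter_group,
                }
                for r in rs
            )
    return pd.DataFrame(rows)


def plot_treatment(results: pd.DataFrame, gene: str, treatment: str, path) -> None:
    """Bar plot of mean folds +/- SD over timepoints for one treatment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = results[(results["gene"] == gene) & (results["treatment"] == treatment)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(
        [str(t) for t in sel["timepoint_h"]],
        sel["mean_fold"],
        yerr=sel["sd_fold"],
        capsize=3,
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("fold change (2^-ddCt)")
    ax.set_title(f"{gene} under {treatment}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
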
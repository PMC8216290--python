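"""Pulldown-enrichment statistics for amber-suppressed proteomes.

The experimental design behind the training data crosses two factors:
cell line (a *treated* line carrying the orthogonal synthetase/tRNA
pair and fed the ncAA, versus a *control* line without it) and sample
type (streptavidin *pulldown* of chemically tagged proteins versus the
matched *full proteome*).  Per-replicate log2 LFQ intensities feed a
fixed pipeline:

1. filter proteins quantified fewer than ``min_per_group`` times in
   every replicate set;
2. (full proteomes only) impute missing values from a down-shifted,
   narrowed Gaussian per sample column;
3. normalize each pulldown replicate by subtracting its matched
   full-proteome replicate, removing expression-level effects;
4. test normalized treated vs control replicates per protein with a
   pooled-variance two-sided Student's t-test; p < 0.01 calls a
   protein significantly enriched (the amberome);
5. attach stop-codon sequence contexts to build the regression
   training table.

Full-proteome differential expression uses the SAM-style S0-moderated
t statistic with a permutation-estimated FDR.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ipass.contexts import SequenceContext, dedupe_contexts

GROUPS = (
    "pulldown_treated",
    "pulldown_control",
    "proteome_treated",
    "proteome_control",
)

P_CUTOFF = 0.01


@dataclass
class LfqMatrix:
    """Proteins x samples matrix of log2 LFQ intensities.

    ``design`` is indexed by sample (column) name with columns
    ``group`` (one of :data:`GROUPS`) and ``replicate`` (int);
    pulldown and proteome columns of the same line pair by replicate
    index.  Missing values are NaN.
    """

    data: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("empty LFQ matrix")
        missing = set(self.data.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design entry: {sorted(missing)}")
        bad = set(self.design["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        dup = self.design.reset_index().duplicated(subset=["group", "replicate"])
        if dup.any():
            raise ValueError("duplicate (group, replicate) in design")

    def columns_of(self, group: str) -> list[str]:
        sel = self.design[self.design["group"] == group]
        return list(sel.sort_values("replicate").index)

    def values_of(self, group: str) -> pd.DataFrame:
        return self.data[self.columns_of(group)]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a YAML/JSON sample sheet: {sample: {group, replicate}}."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    df = pd.DataFrame.from_dict(raw, orient="index")
    df.index.name = "sample"
    return df[["group", "replicate"]]


def read_lfq(table_path: str | Path, sheet_path: str | Path) -> LfqMatrix:
    """Read a wide TSV/CSV (protein column + one column per sample)."""
    sep = "," if str(table_path).endswith(".csv") else "\t"
    df = pd.read_csv(table_path, sep=sep, comment="#")
    df = df.set_index(df.columns[0])
    return LfqMatrix(data=df.astype(float), design=read_sample_sheet(sheet_path))


def filter_min_valid(
    m: LfqMatrix, min_per_group: int = 2
) -> tuple[LfqMatrix, list[str]]:
    """Keep proteins with >= ``min_per_group`` values in at least one
    replicate set; returns (filtered matrix, dropped protein ids)."""
    groups = m.design["group"].unique()
    counts = pd.DataFrame(
        {g: m.values_of(g).notna().sum(axis=1) for g in groups}
    )
    keep = (counts >= min_per_group).any(axis=1)
    dropped = list(m.data.index[~keep])
    if keep.sum() == 0:
        raise ValueError("no proteins survive the minimum-valid-values filter")
    return LfqMatrix(data=m.data.loc[keep].copy(), design=m.design), dropped


def impute_missing(
    m: LfqMatrix, width: float = 0.2, downshift: float = 1.8, seed: int = 0
) -> LfqMatrix:
    """Impute missing cells column-wise from N(mu - downshift*sd, (width*sd)^2).

    Mimics missing-at-low-abundance: imputed values sit in the lower
    tail of each sample's observed distribution.  Deterministic for a
    given seed; observed cells are untouched.
    """
    rng = np.random.default_rng(seed)
    data = m.data.copy()
    for col in data.columns:
        v = data[col]
        obs = v.dropna()
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has < 2 observed values")
        if v.isna().any():
            mu, sd = obs.mean(), obs.std(ddof=1)
            idx = v.index[v.isna()]
            data.loc[idx, col] = rng.normal(
                mu - downshift * sd, width * sd, size=len(idx)
            )
    return LfqMatrix(data=data, design=m.design)


def normalize_to_proteome(m: LfqMatrix) -> dict[str, pd.DataFrame]:
    """Per-replicate pulldown minus matched full-proteome values.

    Returns ``{"treated": ..., "control": ...}`` DataFrames (proteins x
    replicates).  The subtraction cancels protein abundance, leaving
    pure pulldown enrichment; adding any per-replicate constant to both
    members of a pair leaves the result unchanged.
    """
    out: dict[str, pd.DataFrame] = {}
    for line in ("treated", "control"):
        pull = m.design[m.design["group"] == f"pulldown_{line}"]
        prot = m.design[m.design["group"] == f"proteome_{line}"]
        pull_reps = dict(zip(pull["replicate"], pull.index))
        prot_reps = dict(zip(prot["replicate"], prot.index))
        if set(pull_reps) != set(prot_reps):
            odd = set(pull_reps) ^ set(prot_reps)
            raise ValueError(
                f"unpaired {line} replicate(s): {sorted(odd)} — every pulldown "
                "replicate needs a matched full-proteome replicate"
            )
        cols = {}
        for r in sorted(pull_reps):
            cols[r] = m.data[pull_reps[r]] - m.data[prot_reps[r]]
        out[line] = pd.DataFrame(cols)
    return out


def _pooled_t_rows(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sided t-test with NaN handling.

    Returns (mean difference, p, t, zero-variance flag).  Rows with
    < 2 values in either group get NaN.  Zero pooled variance: equal
    means -> t=0, p=1; unequal means -> p=0, flagged.
    """
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        ss1 = np.nansum((a - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((b - m2[:, None]) ** 2, axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    diff = m1 - m2
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = ok & (se == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    # zero pooled variance: limit conventions
    t = np.where(zero & (diff == 0), 0.0, t)
    p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    t = np.where(ok, t, np.nan)
    p = np.where(ok, p, np.nan)
    diff = np.where(ok, diff, np.nan)
    return diff, p, t, zero


def enrichment_test(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    p_cutoff: float = P_CUTOFF,
) -> pd.DataFrame:
    """Pooled two-sample Student's t-test of normalized replicates.

    Input frames are proteins x replicates (from
    :func:`normalize_to_proteome`).  Returns a frame indexed by protein
    with ``mean_lfc`` (mean treated - mean control), ``p_value``,
    ``t``, ``enriched`` (p < cutoff) and ``zero_variance``.
    """
    treated, control = treated.align(control, join="inner", axis=0)
    diff, p, t, zero = _pooled_t_rows(
        treated.to_numpy(float), control.to_numpy(float)
    )
    return pd.DataFrame(
        {
            "mean_lfc": diff,
            "p_value": p,
            "t": t,
            "enriched": p < p_cutoff,
            "zero_variance": zero,
        },
        index=treated.index,
    )


def sorte_enrichment(m: LfqMatrix, p_cutoff: float = P_CUTOFF, min_per_group: int = 2) -> pd.DataFrame:
    """The full pulldown branch: filter, normalize, test (observed values only)."""
    filtered, _ = filter_min_valid(m, min_per_group)
    norm = normalize_to_proteome(filtered)
    return enrichment_test(norm["treated"], norm["control"], p_cutoff)


def perseus_style_de(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    s0: float = 1.0,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style moderated t-test with permutation-estimated FDR.

    The statistic is d = (mean_t - mean_c) / (pooled SE + s0); the s0
    offset damps proteins whose nominal t is large only because their
    variance is tiny.  The null distribution of |d| is built by
    permuting column labels (the observed assignment and its mirror
    are excluded — they reproduce the signal, not the null); a protein
    is significant iff |d| clears the largest threshold whose
    estimated FDR (mean null exceedances / observed exceedances) is
    <= ``fdr``.  Inputs must be complete (imputed) matrices.
    """
    treated, control = treated.align(control, join="inner", axis=0)
    a = treated.to_numpy(float)
    b = control.to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("perseus_style_de requires complete (imputed) matrices")
    n1, n2 = a.shape[1], b.shape[1]
    if math.comb(n1 + n2, n1) < 10:
        raise ValueError(
            "fewer than 10 distinct label permutations; use exact enumeration"
        )

    def _d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        m1, m2 = x.mean(axis=1), y.mean(axis=1)
        ss = ((x - m1[:, None]) ** 2).sum(axis=1) + ((y - m2[:, None]) ** 2).sum(axis=1)
        se = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
        return (m1 - m2) / (se + s0)

    d_obs = _d(a, b)
    pooled = np.concatenate([a, b], axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(d_obs)))
    excluded = {frozenset(range(n1)), frozenset(range(n1, n1 + n2))}
    for i in range(n_perm):
        while True:
            perm = rng.permutation(n1 + n2)
            if frozenset(perm[:n1]) not in excluded:
                break
        null[i] = _d(pooled[:, perm[:n1]], pooled[:, perm[n1:]])
    abs_obs = np.abs(d_obs)
    abs_null = np.abs(null)
    order = np.argsort(abs_obs)[::-1]
    threshold = np.inf
    flat_null = np.sort(abs_null.ravel())
    for rank, idx in enumerate(order, start=1):
        c = abs_obs[idx]
        # mean over permutations of #{|d_null| >= c} = total exceedances / n_perm
        exceed = len(flat_null) - np.searchsorted(flat_null, c, side="left")
        est_fdr = (exceed / n_perm) / rank
        if est_fdr <= fdr:
            threshold = c
    sig = abs_obs >= threshold
    return pd.DataFrame(
        {"d": d_obs, "significant": sig, "threshold": threshold},
        index=treated.index,
    )


def attach_contexts(
    records: pd.DataFrame,
    contexts: Sequence[tuple[str, SequenceContext]],
    p_cutoff: float = P_CUTOFF,
) -> dict[str, pd.DataFrame]:
    """Join enrichment records with sequence contexts into training tables.

    ``records`` is indexed by protein id with ``mean_lfc`` and
    ``p_value`` columns.  The join is inner; isoform contexts are
    deduplicated per protein but a protein may legitimately contribute
    several distinct contexts (one row each).  Conflicting stop-codon
    annotation within one protein is an error.  Returns a dict with
    ``enriched`` (p < cutoff), ``background`` and ``unresolved``
    (record ids with no context) tables.
    """
    ctx = dedupe_contexts(list(contexts))
    stops: dict[str, set] = {}
    for pid, c in ctx:
        stops.setdefault(pid, set()).add(c.stop)
    conflicts = sorted(pid for pid, s in stops.items() if len(s) > 1)
    if conflicts:
        raise ValueError(f"conflicting stop codons for protein(s): {conflicts}")
    rows = []
    for pid, c in ctx:
        if pid in records.index:
            rec = records.loc[pid]
            rows.append(
                {
                    "protein_id": pid,
                    "mean_lfc": rec["mean_lfc"],
                    "p_value": rec["p_value"],
                    "enriched": rec["p_value"] < p_cutoff,
                    "stop": c.stop,
                    "context_m6_p9": str(c),
                    "upstream": c.upstream,
                    "downstream": c.downstream,
                    "gc": c.gc,
                }
            )
    cols = [
        "protein_id", "mean_lfc", "p_value", "enriched", "stop",
        "context_m6_p9", "upstream", "downstream", "gc",
    ]
    table = pd.DataFrame(rows, columns=cols)
    resolved = set(table["protein_id"])
    unresolved = records.loc[[pid for pid in records.index if pid not in resolved]]
    return {
        "enriched": table[table["enriched"]].reset_index(drop=True),
        "background": table[~table["enriched"]].reset_index(drop=True),
        "unresolved": unresolved,
    }


def stop_codon_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Stop-codon composition and fold-change summaries per fraction.

    ``records`` needs ``stop``, ``enriched`` and ``mean_lfc`` columns.
    Returns one row per (fraction, stop codon) with count, the fraction
    of that stop within its enrichment class, and LFC summaries.
    """
    if "enriched" not in records:
        raise ValueError("records need an 'enriched' column")
    rows = []
    for frac_name, sub in (
        ("enriched", records[records["enriched"]]),
        ("background", records[~records["enriched"]]),
    ):
        total = len(sub)
        for stop, grp in sub.groupby("stop"):
            rows.append(
                {
                    "fraction": frac_name,
                    "stop": stop,
                    "count": len(grp),
                    "proportion": len(grp) / total if total else np.nan,
                    "mean_lfc_mean": grp["mean_lfc"].mean(),
                    "mean_lfc_median": grp["mean_lfc"].median(),
                    "mean_lfc_sd": grp["mean_lfc"].std(ddof=1),
                }
            )
    return pd.DataFrame(rows)
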
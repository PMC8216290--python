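"""Dual-fluorescence reporter arithmetic.

The reporter expresses mScarlet (mSc), the gene of interest with an
in-frame amber codon, and mNeonGreen (mNG) as one transcript with
self-cleaving 2A peptides between the segments: full-length mNG is
made only when the UAG is read through, while mSc reports transcript
and translation level.  From per-replicate mean fluorescence
intensities (MFIs):

* RRE (relative readthrough efficiency) =
  (mNG/mSc of the amber construct) / (mNG/mSc of the matched wild-type
  construct) — a ratio of ratios, invariant to instrument gain;
* incorporation efficiency IE = RRE(+ncAA) - RRE(-ncAA), subtracting
  background readthrough by near-cognate tRNAs;
* the fold change between two efficiencies is the odds ratio
  IE_max(1-IE_min) / (IE_min(1-IE_max)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PLUS, MINUS = "plus_ncAA", "minus_ncAA"
CONDITIONS = (PLUS, MINUS)


@dataclass(frozen=True)
class ReporterRecord:
    """MFI pair for one construct/condition/replicate."""

    construct_id: str
    condition: str
    replicate: int
    mfi_mSc: float
    mfi_mNG: float
    is_wt: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.mfi_mSc <= 0 or self.mfi_mNG <= 0:
            raise ValueError("MFIs must be positive")


def rre(amber: ReporterRecord, wt: ReporterRecord) -> float:
    """Relative readthrough efficiency of an amber construct against its
    matched wild-type construct (same condition)."""
    if amber.condition != wt.condition:
        raise ValueError(
            f"condition mismatch: {amber.condition} vs {wt.condition}"
        )
    return (amber.mfi_mNG / amber.mfi_mSc) / (wt.mfi_mNG / wt.mfi_mSc)


def incorporation_efficiency(rre_plus: float, rre_minus: float) -> float:
    """Background-corrected efficiency: RRE(+ncAA) - RRE(-ncAA).

    May come out negative when background readthrough exceeds the
    +ncAA signal; the value is reported as-is.
    """
    return rre_plus - rre_minus


def fold_change(ie_a: float, ie_b: float) -> float:
    """Odds-ratio fold change between two incorporation efficiencies.

    With IE_max/IE_min assigned from the pair:
    [IE_max (1-IE_min)] / [IE_min (1-IE_max)].  Symmetric in argument
    order and >= 1.  Both efficiencies must lie strictly in (0, 1).
    """
    for v in (ie_a, ie_b):
        if not (0.0 < v < 1.0):
            raise ValueError(f"IE {v} outside (0,1): odds undefined")
    hi, lo = max(ie_a, ie_b), min(ie_a, ie_b)
    return (hi * (1.0 - lo)) / (lo * (1.0 - hi))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    need = {"construct_id", "condition", "replicate", "mfi_mSc", "mfi_mNG", "is_wt"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing reporter columns: {sorted(missing)}")
    if (df["mfi_mSc"] <= 0).any() or (df["mfi_mNG"] <= 0).any():
        raise ValueError("MFIs must be positive")
    return df


def replicate_rre(records) -> pd.DataFrame:
    """Per-replicate RREs for every amber construct/condition.

    Each amber row is matched to the wild-type row of the same
    construct, condition and replicate.
    """
    df = _records_frame(records)
    df["ratio"] = df["mfi_mNG"] / df["mfi_mSc"]
    amber = df[~df["is_wt"]]
    wt = df[df["is_wt"]].set_index(["construct_id", "condition", "replicate"])[
        "ratio"
    ]
    rows = []
    for r in amber.itertuples():
        key = (r.construct_id, r.condition, r.replicate)
        if key not in wt.index:
            raise ValueError(f"missing wild-type partner for {key}")
        rows.append(
            {
                "construct_id": r.construct_id,
                "condition": r.condition,
                "replicate": r.replicate,
                "rre": r.ratio / wt.loc[key],
            }
        )
    return pd.DataFrame(rows)


def summarize(
    records,
    scores: dict[str, float] | None = None,
    reference: str | None = None,
    per_replicate: bool = True,
) -> dict:
    """Per-construct summary: mean RREs, mean IE, n, optional fold
    changes vs a reference and score correlation.

    With ``per_replicate`` (default) IE is computed replicate-wise
    (RRE+ minus RRE- within each replicate) and then averaged; the
    alternative averages RREs per condition first and subtracts the
    means.  When a ``scores`` mapping (construct -> model score) is
    given, the squared Pearson correlation of mean IE vs score is
    reported as ``r2``.
    """
    rrep = replicate_rre(records)
    wide = rrep.pivot_table(
        index=["construct_id", "replicate"], columns="condition", values="rre"
    )
    for cond in CONDITIONS:
        if cond not in wide:
            raise ValueError(f"no {cond} measurements present")
    rows = []
    for cid, grp in wide.groupby(level="construct_id"):
        plus = grp[PLUS].dropna()
        minus = grp[MINUS].dropna()
        if per_replicate:
            ie_rep = (grp[PLUS] - grp[MINUS]).dropna()
            mean_ie = ie_rep.mean()
            sd_ie = ie_rep.std(ddof=1)
            n = len(ie_rep)
        else:
            mean_ie = plus.mean() - minus.mean()
            sd_ie = np.nan
            n = min(len(plus), len(minus))
        rows.append(
            {
                "construct_id": cid,
                "mean_rre_plus": plus.mean(),
                "mean_rre_minus": minus.mean(),
                "mean_ie": mean_ie,
                "sd_ie": sd_ie,
                "n": n,
            }
        )
    table = pd.DataFrame(rows).set_index("construct_id")
    if reference is not None:
        ref_ie = table.loc[reference, "mean_ie"]
        table["fold_vs_reference"] = [
            fold_change(ie, ref_ie)
            if 0 < ie < 1 and 0 < ref_ie < 1
            else np.nan
            for ie in table["mean_ie"]
        ]
    out: dict = {"table": table}
    if scores is not None:
        joined = table.join(pd.Series(scores, name="score"), how="inner")
        if len(joined) >= 3:
            r = np.corrcoef(joined["score"], joined["mean_ie"])[0, 1]
            out["r2"] = float(r**2)
            out["n_scored"] = int(len(joined))
    return out
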
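"""Synthetic data generators.

Every generator is a pure function of its arguments (seed included)
and emulates the statistical structure the analysis modules assume:
uniform sense-codon contexts, responses from a planted linear model on
the scaled feature encoding plus Gaussian noise, four-matrix LFQ
experiments (pulldown/proteome x treated/control) with
missing-at-low-abundance values, and reporter MFI quadruples with
multiplicative lognormal noise.  Noise is Gaussian on the log2 scales
(LFQ, MFI) throughout, the conventional assumption for both data
types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ipass.amberome import GROUPS, LfqMatrix
from ipass.contexts import AMBER, SENSE_CODONS, STOP_CODONS, SequenceContext
from ipass.model import N_FEATURES, Scaler, encode_matrix, fit_scaler
from ipass.reporter import MINUS, PLUS

#: background stop-codon usage of mammalian transcriptomes (UAA, UAG, UGA)
STOP_USAGE = {"UAA": 0.30, "UAG": 0.23, "UGA": 0.47}


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth linear model for parameter-recovery experiments."""

    weights: np.ndarray  # 52 weights on the scaled feature space
    intercept: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape != (N_FEATURES,):
            raise ValueError(f"weights must have shape ({N_FEATURES},)")
        object.__setattr__(self, "weights", w)


def random_planted_model(
    seed: int, noise_sd: float = 0.1, weight_sd: float = 0.5, intercept: float = 1.0
) -> PlantedModel:
    """Random ground truth: iid Normal(0, weight_sd) weights.

    The three stop-indicator weights are zeroed — amber-only training
    data cannot identify them.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, weight_sd, N_FEATURES)
    w[48:51] = 0.0
    return PlantedModel(weights=w, intercept=intercept, noise_sd=noise_sd, seed=seed)


def gen_contexts(
    n: int, seed: int, stop_policy: str = "amber_only"
) -> list[SequenceContext]:
    """Draw contexts uniformly over valid (stop-free) flanking 12-mers.

    Each of the four in-frame flanking codons is uniform over the 61
    sense codons; the stop is UAG under ``amber_only`` or uniform over
    the three stops under ``all``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if stop_policy not in ("amber_only", "all"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(SENSE_CODONS), size=(n, 4))
    stops = (
        [AMBER] * n
        if stop_policy == "amber_only"
        else [STOP_CODONS[i] for i in rng.integers(0, 3, size=n)]
    )
    return [
        SequenceContext(
            SENSE_CODONS[a] + SENSE_CODONS[b], s, SENSE_CODONS[c] + SENSE_CODONS[d]
        )
        for (a, b, c, d), s in zip(idx, stops)
    ]


def gen_training_table(
    planted: PlantedModel, n: int, seed: int
) -> tuple[list[SequenceContext], np.ndarray, dict]:
    """Contexts plus responses from the planted model.

    The response is intercept + w . scaled features + N(0, noise_sd),
    with the scaler fit on the generated design itself.  The indicator
    encoding is collinear (each position's four indicators sum to one,
    and GC is a linear combination of indicators), so a weight vector
    is only identifiable up to the design's null space; the planted
    weights are therefore projected onto the row space of the scaled
    design — the minimum-norm representative of their equivalence
    class — and that representative is what ``truth["weights"]``
    reports and what recovery is measured against.
    """
    contexts = gen_contexts(n, seed)
    X = encode_matrix(contexts)
    scaler = fit_scaler(X)
    Xs = scaler.transform(X)
    w_ident, *_ = np.linalg.lstsq(Xs, Xs @ planted.weights, rcond=None)
    signal = planted.intercept + Xs @ w_ident
    rng = np.random.default_rng(seed + 1)
    y = signal + rng.normal(0.0, planted.noise_sd, n)
    truth = {"scaler": scaler, "signal": signal, "weights": w_ident}
    return contexts, y, truth


def gen_lfq_experiment(
    n_proteins: int = 400,
    n_reps: int = 4,
    frac_amber_enriched: float = 0.1,
    effect_lfc: float = 3.0,
    missing_rate: float = 0.1,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> tuple[LfqMatrix, pd.DataFrame]:
    """Simulate a four-matrix pulldown/proteome x treated/control design.

    A shared per-protein baseline abundance underlies all four sample
    groups; the planted "amber-suppressed" fraction receives
    ``effect_lfc`` extra log2 units in the treated pulldown only.
    Missingness is biased toward low-abundance proteins (cell missing
    probability proportional to 1 - abundance percentile, mean
    ``missing_rate``).  Returns the matrix and a truth table with the
    planted enrichment flag, a stop-codon annotation (UAG for planted
    proteins, mammalian-usage frequencies otherwise) and a sequence
    context per protein.
    """
    if not 0 <= frac_amber_enriched <= 1 or not 0 <= missing_rate < 1:
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    n_enriched = int(round(frac_amber_enriched * n_proteins))
    enriched = np.zeros(n_proteins, bool)
    enriched[rng.choice(n_proteins, n_enriched, replace=False)] = True

    baseline = rng.normal(26.0, 3.0, n_proteins)
    # pulldown capture differs from expression level by a protein offset
    pull_offset = rng.normal(-2.0, 1.0, n_proteins)

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for group in GROUPS:
        base = baseline + (pull_offset if group.startswith("pulldown") else 0.0)
        shift = effect_lfc * enriched if group == "pulldown_treated" else 0.0
        for r in range(1, n_reps + 1):
            name = f"{group}_{r}"
            columns[name] = base + shift + rng.normal(0.0, noise_sd, n_proteins)
            design_rows.append({"sample": name, "group": group, "replicate": r})
    data = pd.DataFrame(columns, index=ids)

    # missing-at-low-abundance: probability decays with abundance rank
    pct = pd.Series(baseline).rank(pct=True).to_numpy()
    p_miss = np.clip(2.0 * missing_rate * (1.0 - pct), 0.0, 0.95)
    if missing_rate > 0:
        mask = rng.random(data.shape) < p_miss[:, None]
        data = data.mask(mask)

    stops = np.where(
        enriched,
        AMBER,
        rng.choice(list(STOP_USAGE), n_proteins, p=list(STOP_USAGE.values())),
    )
    contexts = gen_contexts(n_proteins, seed + 7, stop_policy="amber_only")
    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "enriched_truth": enriched,
            "stop": stops,
            "context_m6_p9": [
                c.upstream + s + c.downstream for c, s in zip(contexts, stops)
            ],
        }
    ).set_index("protein_id")
    design = pd.DataFrame(design_rows).set_index("sample")
    return LfqMatrix(data=data, design=design), truth


def gen_reporter_table(
    true_rre_plus,
    true_rre_minus,
    n_reps: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate tidy reporter MFI records from target RREs.

    ``true_rre_plus``/``true_rre_minus`` are either scalars (a single
    construct ``ctx1``) or dicts construct -> RRE.  MFIs are drawn
    around nominal instrument values (mSc 1e4; wt mNG/mSc ratio 1)
    with multiplicative lognormal noise of coefficient of variation
    ``cv``; matched wild-type rows are included.
    """
    if not isinstance(true_rre_plus, dict):
        true_rre_plus = {"ctx1": float(true_rre_plus)}
        true_rre_minus = {"ctx1": float(true_rre_minus)}
    if set(true_rre_plus) != set(true_rre_minus):
        raise ValueError("construct sets differ between +ncAA and -ncAA")
    for d in (true_rre_plus, true_rre_minus):
        for cid, v in d.items():
            if not 0 < v < 1.5:
                raise ValueError(f"RRE {v} for {cid!r} outside (0, 1.5)")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))  # lognormal with unit mean, given CV

    def noisy(x: float) -> float:
        if cv == 0:
            return x
        return x * rng.lognormal(-(sigma**2) / 2.0, sigma)

    msc0, ratio_wt = 1.0e4, 1.0
    rows = []
    for cid in true_rre_plus:
        for cond, target in ((PLUS, true_rre_plus[cid]), (MINUS, true_rre_minus[cid])):
            for r in range(1, n_reps + 1):
                rows.append(
                    {
                        "construct_id": cid,
                        "is_wt": True,
                        "condition": cond,
                        "replicate": r,
                        "mfi_mSc": noisy(msc0),
                        "mfi_mNG": noisy(msc0 * ratio_wt),
                    }
                )
                rows.append(
                    {
                        "construct_id": cid,
                        "is_wt": False,
                        "condition": cond,
                        "replicate": r,
                        "mfi_mSc": noisy(msc0),
                        "mfi_mNG": noisy(msc0 * ratio_wt * target),
                    }
                )
    return pd.DataFrame(rows)
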
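"""T2/T1/T0 cross-validation of hybrid prediction.

A replicate samples nD group-1 and nF group-2 lines, draws the training
hybrids from the crosses of the sampled lines, and classifies every
remaining hybrid by how many of its parents appear among the training
hybrids' parents: T2 (both), T1 (exactly one), T0 (neither).  Predictive
ability per class is the Pearson correlation of predicted and observed
values divided by the broad-sense heritability (or its square root; both
conventions are supported and the choice is recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LineGenotypes, HybridPedigree, PhenotypeTable
from .inference import ChainConfig, assemble_model, gibbs_fit, summarize_fit, predict_hybrids

__all__ = ["CvSplit", "CvResult", "make_cv_split", "predictive_ability", "run_cv"]

CLASSES = ("T2", "T1", "T0")


@dataclass
class CvSplit:
    replicate: int
    seed: int
    training: list[str]
    test_class: dict[str, str]  # remaining hybrid -> {"T2","T1","T0"}

    def test_ids(self, cls: str) -> list[str]:
        return [h for h, c in self.test_class.items() if c == cls]


@dataclass
class CvResult:
    model_code: str
    divisor: str
    h2: float
    replicates: int
    ability: dict[str, tuple[float, float]] = field(default_factory=dict)  # class -> (mean, SD)
    per_replicate: dict[str, list[float]] = field(default_factory=dict)


def make_cv_split(
    ped: HybridPedigree,
    n_train: int,
    nD: int,
    nF: int,
    seed: int,
    replicate: int = 0,
    max_retries: int = 50,
) -> CvSplit:
    """Sample nD group-1 and nF group-2 lines, then ``n_train`` hybrids
    uniformly from the crosses among the sampled lines; label the rest.

    If the candidate pool is smaller than ``n_train`` the line sample is
    redrawn, up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    lines1 = sorted({ped.parent1[h] for h in ped.hybrid_ids})
    lines2 = sorted({ped.parent2[h] for h in ped.hybrid_ids})
    if nD > len(lines1) or nF > len(lines2):
        raise ValueError(
            f"cannot sample {nD}/{nF} lines from {len(lines1)}/{len(lines2)} available"
        )
    pool: list[str] = []
    for attempt in range(max_retries):
        s1 = set(rng.choice(lines1, size=nD, replace=False))
        s2 = set(rng.choice(lines2, size=nF, replace=False))
        pool = [h for h in ped.hybrid_ids
                if ped.parent1[h] in s1 and ped.parent2[h] in s2]
        if len(pool) >= n_train:
            break
    else:
        raise RuntimeError(
            f"after {max_retries} line resamples the largest candidate pool "
            f"had {len(pool)} hybrids (< n_train={n_train})"
        )
    training = sorted(rng.choice(pool, size=n_train, replace=False))
    train_p1 = {ped.parent1[h] for h in training}
    train_p2 = {ped.parent2[h] for h in training}
    test_class = {}
    train_set = set(training)
    for h in ped.hybrid_ids:
        if h in train_set:
            continue
        k = (ped.parent1[h] in train_p1) + (ped.parent2[h] in train_p2)
        test_class[h] = f"T{k}"
    return CvSplit(replicate, seed, list(training), test_class)


def predictive_ability(
    pred: np.ndarray, obs: np.ndarray, H2: float, divisor: str = "h2"
) -> float:
    """Pearson correlation of predicted and observed values, divided by H2
    (``divisor="h2"``), by sqrt(H2) (``"sqrt_h2"``), or undivided (``"none"``).

    Returns NaN when either vector is degenerate (fewer than 3 pairs or zero
    variance).
    """
    if divisor not in ("h2", "sqrt_h2", "none"):
        raise ValueError(f"unknown divisor {divisor!r}")
    if not 0.0 < H2 <= 1.0:
        raise ValueError(f"H2={H2!r} outside (0, 1]")
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 3 or np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return float("nan")
    r = float(np.corrcoef(pred, obs)[0, 1])
    if divisor == "h2":
        return r / H2
    if divisor == "sqrt_h2":
        return r / float(np.sqrt(H2))
    return r


def run_cv(
    g1: LineGenotypes,
    g2: LineGenotypes,
    ped: HybridPedigree,
    phenotypes: PhenotypeTable,
    model_code: str,
    n_train: int,
    nD: int,
    nF: int,
    reps: int = 100,
    chain: ChainConfig | None = None,
    with_r: bool = True,
    divisor: str = "h2",
    h2: float | None = None,
    seed: int = 0,
) -> CvResult:
    """Replicated T2/T1/T0 cross-validation for one model code.

    Split seeds are derived as ``seed + replicate``, so different model
    codes evaluated with the same ``seed`` see identical splits (paired
    comparison).  ``h2``, if not given, is estimated from a full-data fit of
    the most complete GCA model (with r effects).
    """
    chain = chain or ChainConfig()
    if h2 is None:
        full = assemble_model(g1, g2, ped, "GCA:ADAA11AA22AA12", with_r=True)
        fit = gibbs_fit(phenotypes, full, chain)
        h2 = summarize_fit(fit, full, phenotypes).H2_mean

    M = assemble_model(g1, g2, ped, model_code, with_r=with_r)
    obs = phenotypes.to_series()
    per_rep: dict[str, list[float]] = {c: [] for c in CLASSES}
    pheno_set = set(phenotypes.hybrid_ids)
    for rep in range(reps):
        split = make_cv_split(ped, n_train, nD, nF, seed=seed + rep, replicate=rep)
        y_train = phenotypes.subset([h for h in split.training if h in pheno_set])
        rep_chain = ChainConfig(
            chain.n_iter, chain.burn_in, chain.thin, chain.seed + rep,
            chain.prior_df, chain.prior_genetic_share,
        )
        try:
            samples = gibbs_fit(y_train, M, rep_chain)
        except Exception as exc:
            raise RuntimeError(f"model fit failed in replicate {rep}") from exc
        for cls in CLASSES:
            ids = [h for h in split.test_ids(cls) if h in pheno_set]
            if not ids:
                per_rep[cls].append(float("nan"))
                continue
            pred = predict_hybrids(samples, M, ids)
            per_rep[cls].append(
                predictive_ability(pred.to_numpy(), obs.loc[ids].to_numpy(), h2, divisor)
            )

    result = CvResult(model_code, divisor, float(h2), reps, per_replicate=per_rep)
    for cls in CLASSES:
        vals = np.array(per_rep[cls], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            result.ability[cls] = (float("nan"), float("nan"))
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            result.ability[cls] = (float(np.mean(vals)), sd)
    return result
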
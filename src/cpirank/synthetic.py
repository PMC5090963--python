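"""Synthetic CPI matrices and indication labels with planted structure.

The generator emulates a docking-score matrix: each target has a baseline
binding free energy (kcal/mol, drawn uniformly from ``score_location``), each
(drug, target) pair a nonnegative binding boost ``b ~ |Normal(0, 1)|`` that
*subtracts* from the score (more negative = stronger binding, the
docking-energy convention), plus Gaussian measurement noise.  Each disease is
assigned ``causal_per_disease`` causal targets; its labels are Bernoulli with

    P(y = 1) = logistic(alpha_j + effect * mean standardized boost over causal targets)

(the boost z-scored to mean 0, sd 1, so ``effect`` is a log-odds slope per
standard unit of binding strength)

where ``alpha_j`` is solved per disease by bisection so the expected
prevalence over the generated drug sample matches ``prevalence`` (tolerance
1e-4).  ``effect = 0`` makes labels independent of scores (a built-in null).
Disease codes are synthetic ICD-9-style strings spread over families
100-699, with an optional decoy block in the excluded 780-999 range to
exercise the endpoint range filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpirank.io import CPIMatrix, IndicationLabels

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "permute_labels"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 300
    n_targets: int = 50
    n_diseases: int = 20
    causal_per_disease: int = 3
    effect: float = 3.0
    prevalence: float = 0.1
    score_location: tuple[float, float] = (-9.0, -5.0)
    score_noise_sd: float = 0.1
    diseases_per_family: int = 2
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.n_diseases) <= 0:
            raise ValueError("all counts must be positive")
        if not 1 <= self.causal_per_disease <= self.n_targets:
            raise ValueError("causal_per_disease must be in [1, n_targets]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.score_noise_sd <= 0:
            raise ValueError("score_noise_sd must be positive")
        if self.score_location[0] >= self.score_location[1]:
            raise ValueError("score_location must be an increasing interval")
        n_fams = -(-self.n_diseases // self.diseases_per_family)
        if 100 + n_fams - 1 > 699:
            raise ValueError("too many diseases for the 100-699 family block")
        if self.n_decoys > 220:
            raise ValueError("at most 220 decoy families fit in 780-999")


@dataclass
class SyntheticTruth:
    """Planted ground truth consistent with the emitted matrix and labels."""

    disease_codes: list[str]
    causal_targets: dict[str, list[str]]
    binding_strengths: np.ndarray  # drugs x targets latent boosts
    label_matrix: np.ndarray  # drugs x diseases realized 0/1
    alphas: dict[str, float] = field(default_factory=dict)


def _solve_alpha(x: np.ndarray, beta: float, prevalence: float, tol: float = 1e-4) -> float:
    """Bisection for alpha with mean(logistic(alpha + beta*x)) = prevalence."""

    def mean_p(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * x)))))

    lo, hi = -60.0, 60.0
    if not mean_p(lo) <= prevalence <= mean_p(hi):
        raise ValueError("cannot bracket the prevalence intercept")
    while hi - lo > 1e-10:
        mid = (lo + hi) / 2
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if abs(mean_p((lo + hi) / 2) - prevalence) <= tol:
            break
    return (lo + hi) / 2


def generate(config: SyntheticConfig) -> tuple[CPIMatrix, IndicationLabels, SyntheticTruth]:
    """Generate a (CPI matrix, labels, ground truth) triple; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    nd, nt, nj = config.n_drugs, config.n_targets, config.n_diseases

    drug_ids = [f"D{i:04d}" for i in range(nd)]
    target_ids = [f"T{t:03d}" for t in range(nt)]

    lo, hi = config.score_location
    mu = rng.uniform(lo, hi, size=nt)
    boosts = np.abs(rng.standard_normal((nd, nt)))
    noise = rng.normal(0.0, config.score_noise_sd, size=(nd, nt))
    scores = mu[None, :] - boosts + noise
    # standardized strength: half-normal boosts z-scored to mean 0, sd 1,
    # so `effect` is a log-odds slope per standard unit of binding
    z = (boosts - np.sqrt(2.0 / np.pi)) / np.sqrt(1.0 - 2.0 / np.pi)

    codes = [
        f"{100 + j // config.diseases_per_family}.{j % config.diseases_per_family}"
        for j in range(nj)
    ]
    causal: dict[str, list[str]] = {}
    alphas: dict[str, float] = {}
    Y = np.zeros((nd, nj), dtype=int)
    for j, code in enumerate(codes):
        idx = np.sort(rng.choice(nt, size=config.causal_per_disease, replace=False))
        causal[code] = [target_ids[t] for t in idx]
        x = z[:, idx].mean(axis=1)
        alpha = _solve_alpha(x, config.effect, config.prevalence)
        alphas[code] = alpha
        p = 1.0 / (1.0 + np.exp(-(alpha + config.effect * x)))
        Y[:, j] = rng.random(nd) < p

    positives = {
        (drug_ids[i], codes[j]) for i, j in zip(*np.nonzero(Y))
    }
    # decoy endpoints inside the excluded 780-999 range, labels pure noise
    for d in range(config.n_decoys):
        code = f"{780 + d}.0"
        hits = np.nonzero(rng.random(nd) < config.prevalence)[0]
        positives.update((drug_ids[i], code) for i in hits)

    cpi = CPIMatrix(drug_ids=drug_ids, target_ids=target_ids, scores=scores)
    labels = IndicationLabels(drug_universe=frozenset(drug_ids), positives=frozenset(positives))
    truth = SyntheticTruth(
        disease_codes=codes,
        causal_targets=causal,
        binding_strengths=boosts,
        label_matrix=Y,
        alphas=alphas,
    )
    return cpi, labels, truth


def permute_labels(labels: IndicationLabels, seed: int) -> IndicationLabels:
    """Null control: redraw each endpoint's positive drugs uniformly.

    Drug identities are permuted within each endpoint's label column, which
    preserves every endpoint's positive count while destroying any
    drug-feature association.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(labels.drug_universe)
    by_code: dict[str, set[str]] = {}
    for drug, code in labels.positives:
        by_code.setdefault(code, set()).add(drug)
    new_pairs: set[tuple[str, str]] = set()
    for code in sorted(by_code):
        n_pos = len(by_code[code])
        chosen = rng.choice(len(universe), size=n_pos, replace=False)
        new_pairs.update((universe[i], code) for i in chosen)
    return IndicationLabels(drug_universe=labels.drug_universe, positives=frozenset(new_pairs))
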
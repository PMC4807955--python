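"""Case-control data simulation from two-locus penetrance models.

A disease model is a pair of minor-allele frequencies plus a 3x3 penetrance
table f(g_a, g_b) giving the disease probability for each joint genotype.
Genotypes follow Hardy-Weinberg proportions at the stated MAF and loci are
unlinked.  Datasets are drawn retrospectively (fixed case/control counts,
genotypes sampled from the case- and control-conditional distributions), the
design of typical epistasis benchmark data; a prospective population-sampling
mode exists for consistency checks against the model prevalence.

The shipped model families mirror the three benchmark classes with marginal
effects (multiplicative, threshold) and the pure-interaction (XOR-like)
class without marginal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import GenotypeDataset

__all__ = [
    "PenetranceModel",
    "hwe_genotype_probs",
    "compute_prevalence",
    "compute_heritability",
    "simulate_dataset",
    "simulate_population",
    "multiplicative_model",
    "threshold_model",
    "interaction_model",
]


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2).

    ``maf`` is the minor-allele frequency q, required in (0, 0.5].
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"minor-allele frequency must be in (0, 0.5], got {maf}")
    q = float(maf)
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


@dataclass
class PenetranceModel:
    """MAFs + 3x3 penetrance table defining a two-locus disease model.

    ``penetrance[ga, gb]`` is P(disease | ga copies of minor allele at locus
    A, gb at locus B).  ``background_maf_range`` bounds the uniform draw of
    MAFs for the non-causal SNPs added around the causal pair.
    """

    maf_a: float
    maf_b: float
    penetrance: np.ndarray
    background_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.penetrance.shape != (3, 3):
            raise ValueError("penetrance must be a 3x3 table")
        if ((self.penetrance < 0) | (self.penetrance > 1)).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        for maf in (self.maf_a, self.maf_b):
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("background MAF range must satisfy 0 < lo <= hi <= 0.5")

    def joint_genotype_probs(self) -> np.ndarray:
        """3x3 joint HWE genotype probabilities for the causal pair."""
        return np.outer(hwe_genotype_probs(self.maf_a), hwe_genotype_probs(self.maf_b))

    @property
    def prevalence(self) -> float:
        return compute_prevalence(self)

    @property
    def heritability(self) -> float:
        return compute_heritability(self)

    @classmethod
    def from_yaml(cls, path) -> tuple["PenetranceModel", dict]:
        """Load a model (and any simulation defaults) from a YAML/JSON file.

        Recognized keys: ``maf_a``, ``maf_b``, ``penetrance`` (3 rows of 3),
        ``background_maf_range``; the remaining keys (e.g. ``n_cases``,
        ``n_controls``, ``n_snps``, ``seed``) are returned untouched as
        simulation defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of model parameters")
        kwargs = {
            "maf_a": raw.pop("maf_a"),
            "maf_b": raw.pop("maf_b"),
            "penetrance": raw.pop("penetrance"),
        }
        if "background_maf_range" in raw:
            kwargs["background_maf_range"] = tuple(raw.pop("background_maf_range"))
        return cls(**kwargs), raw

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "maf_a": float(self.maf_a),
                    "maf_b": float(self.maf_b),
                    "penetrance": [[float(x) for x in row] for row in self.penetrance],
                    "background_maf_range": [float(x) for x in self.background_maf_range],
                },
                fh,
            )


def compute_prevalence(model: PenetranceModel) -> float:
    """Population disease prevalence K = sum_{a,b} P(ga) P(gb) f(a, b)."""
    return float(np.sum(model.joint_genotype_probs() * model.penetrance))


def compute_heritability(model: PenetranceModel) -> float:
    """Broad-sense heritability H^2 = Var(f) / (K (1 - K)).

    Var(f) is the genotype-frequency-weighted variance of the penetrance over
    the nine joint genotype cells and K the prevalence; this is the standard
    descriptor used to grade simulated epistasis models by difficulty.  It is
    recorded as a model property only — the detector never sees it.
    """
    w = model.joint_genotype_probs()
    k = float(np.sum(w * model.penetrance))
    if not 0.0 < k < 1.0:
        raise ValueError(f"heritability undefined at prevalence {k}")
    var = float(np.sum(w * (model.penetrance - k) ** 2))
    return var / (k * (1.0 - k))


def _sample_causal_genotypes(
    model: PenetranceModel, n: int, case: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n joint genotypes from P(g | phenotype) for the causal pair."""
    joint = model.joint_genotype_probs().ravel()
    f = model.penetrance.ravel()
    weights = joint * (f if case else 1.0 - f)
    total = weights.sum()
    if total <= 0.0:
        kind = "case" if case else "control"
        raise ValueError(
            f"penetrance model assigns zero probability to every {kind} genotype"
        )
    cells = rng.choice(9, size=n, p=weights / total)
    return cells // 3, cells % 3


def simulate_dataset(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    seed: int,
    causal_positions: tuple[int, int] | None = None,
) -> tuple[GenotypeDataset, tuple[int, int]]:
    """Simulate a retrospective case-control dataset with one causal pair.

    Causal genotypes are drawn from the phenotype-conditional distributions
    P(g_a, g_b | case) ∝ P(g_a) P(g_b) f(a,b) and the control analogue with
    1 - f; background SNPs are independent HWE draws at MAFs uniform in
    ``model.background_maf_range``.  The causal pair lands at
    ``causal_positions`` or at two distinct uniform-random columns.

    Returns the dataset and the (sorted, 0-based) causal column pair.
    Deterministic given ``seed``.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs to place a causal pair")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    rng = np.random.default_rng(seed)

    ga_case, gb_case = _sample_causal_genotypes(model, n_cases, True, rng)
    ga_ctrl, gb_ctrl = _sample_causal_genotypes(model, n_controls, False, rng)
    ga = np.concatenate([ga_case, ga_ctrl])
    gb = np.concatenate([gb_case, gb_ctrl])
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    L = n_cases + n_controls

    if causal_positions is None:
        pos = rng.choice(n_snps, size=2, replace=False)
        pos_a, pos_b = int(pos[0]), int(pos[1])
    else:
        pos_a, pos_b = causal_positions
        if pos_a == pos_b or not (0 <= pos_a < n_snps and 0 <= pos_b < n_snps):
            raise ValueError(f"invalid causal positions {causal_positions}")

    lo, hi = model.background_maf_range
    background_mafs = rng.uniform(lo, hi, size=n_snps - 2)
    background = rng.binomial(2, background_mafs, size=(L, n_snps - 2)).astype(np.int8)
    # scatter the canonical [background..., ga, gb] layout: placement is a
    # pure column permutation, so un-permuting recovers the canonical data
    genotypes = np.empty((L, n_snps), dtype=np.int8)
    bg_cols = [c for c in range(n_snps) if c not in (pos_a, pos_b)]
    genotypes[:, bg_cols] = background
    genotypes[:, pos_a] = ga
    genotypes[:, pos_b] = gb

    ds = GenotypeDataset(genotypes, phenotype)
    return ds, (min(pos_a, pos_b), max(pos_a, pos_b))


def simulate_population(
    model: PenetranceModel, n_individuals: int, seed: int
) -> GenotypeDataset:
    """Prospective sampling at the causal pair only: HWE genotypes, then a
    Bernoulli(f) phenotype.  The case fraction converges to the model
    prevalence; used to check the sampler against :func:`compute_prevalence`.
    """
    rng = np.random.default_rng(seed)
    pa = hwe_genotype_probs(model.maf_a)
    pb = hwe_genotype_probs(model.maf_b)
    ga = rng.choice(3, size=n_individuals, p=pa)
    gb = rng.choice(3, size=n_individuals, p=pb)
    phenotype = rng.random(n_individuals) < model.penetrance[ga, gb]
    genotypes = np.column_stack([ga, gb]).astype(np.int8)
    return GenotypeDataset(genotypes, phenotype.astype(np.int8))


# ---------------------------------------------------------------------------
# Model families


def multiplicative_model(
    maf: float, base: float = 0.05, theta: float = 0.5, **kwargs
) -> PenetranceModel:
    """Risk multiplies per disease allele: f = base * (1 + theta)^(ga + gb)."""
    g = np.arange(3)
    pen = base * (1.0 + theta) ** (g[:, None] + g[None, :])
    return PenetranceModel(maf, maf, np.clip(pen, 0.0, 1.0), **kwargs)


def threshold_model(
    maf: float,
    base: float = 0.05,
    elevated: float = 0.3,
    threshold: int = 2,
    **kwargs,
) -> PenetranceModel:
    """Risk jumps once the total count of disease alleles reaches a threshold."""
    g = np.arange(3)
    total = g[:, None] + g[None, :]
    pen = np.where(total >= threshold, elevated, base)
    return PenetranceModel(maf, maf, pen, **kwargs)


def interaction_model(
    maf: float, low: float = 0.02, high: float = 0.6, **kwargs
) -> PenetranceModel:
    """XOR-like pure interaction: risk depends on the parity of ga + gb.

    Penetrance is ``high`` when ga + gb is odd and ``low`` otherwise, so
    neither locus shows a marginal effect at MAF 0.5 and only a weak one at
    other MAFs; association is carried almost entirely by the joint
    distribution.  With the defaults at MAF 0.4 the model has H^2 ≈ 0.39.
    """
    g = np.arange(3)
    odd = (g[:, None] + g[None, :]) % 2 == 1
    pen = np.where(odd, high, low)
    return PenetranceModel(maf, maf, pen, **kwargs)
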
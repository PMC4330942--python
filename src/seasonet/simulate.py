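"""Synthetic seasonal metabolome and trait generator with known ground truth.

The generator emulates the statistical structure the downstream network
analysis assumes: a 12-month series (June through May) with replicate
metabolite profiles per month for three seed states, metabolites organized
in compound-class blocks that share a latent monthly factor, a
summer/winter mean shift, and two physiological traits (germination % and
survival %) scored as binomial counts out of 50 seeds per replicate.

Survival follows an annual sinusoid peaking at a configurable month
(January by default) and collapsing to zero six months away; germination
stays high year-round apart from configurable dips.  Traits are coupled to
chosen metabolite blocks through the blocks' latent monthly factors, with
signed coupling coefficients recorded in the ground truth so recovery of
the planted structure can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import (
    MONTHS, SEED_STATES, SUMMER_MONTHS, WINTER_MONTHS, TRAITS,
    TRAIT_BATCH_SIZE, AbundanceTable, TraitSeries,
    read_abundance_csv, read_traits_csv,
    write_abundance_csv, write_traits_csv, write_metabolite_meta_csv,
    write_ground_truth_json,
)

#: seasonal square wave: +1 in summer, -1 in winter, 0 in shoulder months
SEASON_SIGN = {m: (1.0 if m in SUMMER_MONTHS else -1.0 if m in WINTER_MONTHS else 0.0)
               for m in MONTHS}

_DEFAULT_BLOCK_CLASSES = ("sugar", "amino acid", "organic acid", "flavonoid")


def _default_block_sizes(n_metabolites: int, n_blocks: int = 4) -> list[int]:
    base = n_metabolites // n_blocks
    sizes = [base] * n_blocks
    for i in range(n_metabolites - base * n_blocks):
        sizes[i] += 1
    return sizes


@dataclass
class SimulationConfig:
    """Parameters of the seasonal block-factor model.

    Defaults reproduce the scale of the study design: 12 months, 4
    replicates per month and state, 69 metabolites (so 71 network nodes
    once the two traits are appended) in four compound-class blocks.
    """

    n_months: int = 12
    n_replicates: int = 4
    n_metabolites: int = 69
    block_sizes: list[int] | None = None
    block_classes: tuple[str, ...] = _DEFAULT_BLOCK_CLASSES
    #: per-block factor loading in [0, 1]
    block_loadings: list[float] | None = None
    #: per-block summer/winter mean shift (sign gives the season of peak
    #: abundance: positive = summer-accumulating)
    seasonal_amplitude: list[float] | None = None
    #: per-trait, per-block signed coupling of the trait to the block factor
    trait_couplings: dict[str, list[float]] | None = None
    noise_sd: float = 0.2
    #: sd of the replicate-shared monthly block factor
    month_factor_sd: float = 0.9
    #: sd of the replicate-level factor component
    replicate_factor_sd: float = 0.3
    baseline_low: float = 8.0
    baseline_high: float = 12.0
    #: month of the survival peak; the trough sits six months away
    survival_phase: str = "Jan"
    #: scale of the trait-factor coupling term in the survival latent
    survival_coupling_scale: float = 0.4
    #: steepness of the latent-to-probability squash for survival
    survival_sharpness: float = 0.2
    germination_base: float = 0.90
    germination_dips: dict[str, float] = field(
        default_factory=lambda: {"Nov": 0.765, "May": 0.66})
    germination_coupling_scale: float = 0.2
    #: season-response multiplier per seed state (dry seeds barely move)
    state_season_scale: dict[str, float] = field(
        default_factory=lambda: {"dry": 0.15, "germinated": 1.0, "dehydrated": 1.2})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 2 or self.n_months > 12:
            raise ValueError("n_months must lie in [2, 12]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.block_sizes is None:
            self.block_sizes = _default_block_sizes(
                self.n_metabolites, len(self.block_classes))
        if sum(self.block_sizes) != self.n_metabolites:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, "
                f"expected n_metabolites={self.n_metabolites}")
        nb = len(self.block_sizes)
        if self.block_loadings is None:
            self.block_loadings = [0.9] * nb
        if len(self.block_loadings) != nb:
            raise ValueError("block_loadings must have one entry per block")
        if any(not 0 <= l <= 1 for l in self.block_loadings):
            raise ValueError("block_loadings must lie in [0, 1]")
        if self.seasonal_amplitude is None:
            amps = [0.8, 0.0, 0.6, -0.6]
            self.seasonal_amplitude = (amps * ((nb + 3) // 4))[:nb]
        if len(self.seasonal_amplitude) != nb:
            raise ValueError("seasonal_amplitude must have one entry per block")
        if self.trait_couplings is None:
            surv = [0.0] * nb
            germ = [0.0] * nb
            surv[0] = -0.9            # summer sugar block suppresses survival
            if nb >= 4:
                surv[3] = 0.4         # mild positive coupling to flavonoids
            if nb >= 2:
                germ[1] = 0.9         # germination tracks the amino-acid block
            else:
                germ[0] = 0.9
            self.trait_couplings = {"survival": surv, "germination": germ}
        for trait, cs in self.trait_couplings.items():
            if trait not in TRAITS:
                raise ValueError(f"trait_couplings: unknown trait {trait!r}")
            if len(cs) != nb:
                raise ValueError(f"trait_couplings[{trait!r}] must have one entry per block")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.month_factor_sd < 0 or self.replicate_factor_sd < 0:
            raise ValueError("factor standard deviations must be nonnegative")
        if self.survival_phase not in MONTHS:
            raise ValueError(f"survival_phase must be one of {MONTHS}")
        for m in self.germination_dips:
            if m not in MONTHS:
                raise ValueError(f"germination_dips: unknown month {m!r}")

    @property
    def months(self) -> list[str]:
        return list(MONTHS[: self.n_months])

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def metabolite_names(self) -> list[str]:
        names = []
        for b, (size, cls) in enumerate(zip(self.block_sizes, self.block_classes)):
            slug = cls.replace(" ", "_").replace("/", "_")
            names.extend(f"{slug}_{i + 1:02d}" for i in range(size))
        return names

    @property
    def block_of_metabolite(self) -> dict[str, int]:
        out = {}
        i = 0
        names = self.metabolite_names
        for b, size in enumerate(self.block_sizes):
            for _ in range(size):
                out[names[i]] = b
                i += 1
        return out


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    block_assignment: dict[str, int]
    trait_correlation_signs: dict[tuple[str, int], str]
    seasonal_means: pd.DataFrame          # month x block planted mean shift

    def __post_init__(self) -> None:
        if not self.block_assignment:
            raise ValueError("block_assignment must not be empty")


def _block_factors(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Monthly block factors, decorrelated in-sample when months allow.

    With only 12 monthly values, independent Gaussian factor draws show
    chance cross-correlations of +-0.3 or more, which would blur the
    planted block structure the generator is supposed to plant.  The raw
    draws are therefore orthogonalized (Gram-Schmidt) against the
    intercept, the seasonal square wave, the survival cosine and each
    other, then rescaled to sample sd ``month_factor_sd``.  Real data make
    no such orthogonality promise; the factors are still random, merely
    decorrelated at the planted-design level.
    """
    months = cfg.months
    n_m, n_b = len(months), cfg.n_blocks
    draws = rng.normal(0.0, 1.0, size=(n_m, n_b))
    if n_m < n_b + 4:   # not enough dimensions to orthogonalize
        return (draws * cfg.month_factor_sd).T
    season = np.array([SEASON_SIGN[m] for m in months])
    phase = MONTHS.index(cfg.survival_phase)
    idx = np.array([MONTHS.index(m) for m in months], dtype=float)
    cosine = np.cos(2 * np.pi * (idx - phase) / 12.0)
    basis: list[np.ndarray] = []
    for v in (np.ones(n_m), season, cosine):
        w = v.astype(float).copy()
        for b in basis:
            w -= (w @ b) * b
        norm = np.linalg.norm(w)
        if norm > 1e-10:
            basis.append(w / norm)
    cols = []
    for j in range(n_b):
        h = draws[:, j].copy()
        for b in basis:
            h -= (h @ b) * b
        norm = np.linalg.norm(h)
        if norm < 1e-10:    # essentially impossible for Gaussian draws
            h = draws[:, j]
            norm = np.linalg.norm(h)
        basis.append(h / norm)
        sd = h.std(ddof=0)
        cols.append(h / sd * cfg.month_factor_sd)
    return np.array(cols)


def _survival_probabilities(cfg: SimulationConfig, eta: np.ndarray) -> np.ndarray:
    """Monthly survival probability: annual cosine + coupled block factors.

    The latent is squashed through a normal CDF, which saturates near the
    peak and trough so the planted July collapse / January peak survive the
    coupling noise; the squash is monotone, so rank correlations with the
    coupled blocks are unchanged.
    """
    months = cfg.months
    phase = MONTHS.index(cfg.survival_phase)
    idx = np.array([MONTHS.index(m) for m in months], dtype=float)
    lam = np.cos(2 * np.pi * (idx - phase) / 12.0)
    cs = np.asarray(cfg.trait_couplings["survival"], dtype=float)
    lam = lam + cfg.survival_coupling_scale * (cs @ eta)
    return sps.norm.cdf(lam / cfg.survival_sharpness)


def _germination_probabilities(cfg: SimulationConfig, eta: np.ndarray) -> np.ndarray:
    """Monthly germination probability: high baseline, dip months, coupling."""
    base = np.array([cfg.germination_dips.get(m, cfg.germination_base)
                     for m in cfg.months])
    cg = np.asarray(cfg.trait_couplings["germination"], dtype=float)
    lam = base + cfg.germination_coupling_scale * (cg @ eta)
    return np.clip(lam, 0.02, 0.99)


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[AbundanceTable, TraitSeries, GroundTruth]:
    """Generate one seasonal dataset (all three seed states) plus ground truth.

    Metabolite j of block b in month m, replicate k and state s is

        x = baseline_j + scale_s * amplitude_b * season(m)
            + loading_b * (eta_b(m) + zeta_b(m, k)) + eps

    with season(m) = +1 in summer (Jun-Sep), -1 in winter (Nov-Feb), 0 in
    shoulder months; eta the replicate-shared monthly block factor (shared
    between the germinated and dehydrated states, independent for dry
    seeds) and eps iid Gaussian noise.  Traits couple to the shared eta, so
    trait-metabolite correlations appear in the germinated and dehydrated
    networks but not in the dry-seed network, matching the physiology the
    generator emulates.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    months = cfg.months
    n_m, n_r, n_b = len(months), cfg.n_replicates, cfg.n_blocks
    names = cfg.metabolite_names
    season = np.array([SEASON_SIGN[m] for m in months])
    amps = np.asarray(cfg.seasonal_amplitude, dtype=float)
    loadings = np.asarray(cfg.block_loadings, dtype=float)

    baselines = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=cfg.n_metabolites)
    # monthly block factors: one shared set for germinated+dehydrated seeds,
    # an independent set for dry seeds
    eta_shared = _block_factors(rng, cfg)
    eta_dry = _block_factors(rng, cfg)

    block_of = cfg.block_of_metabolite
    block_idx = np.array([block_of[name] for name in names])

    frames = []
    for state in SEED_STATES:
        eta = eta_dry if state == "dry" else eta_shared
        scale = cfg.state_season_scale.get(state, 1.0)
        zeta = rng.normal(0.0, cfg.replicate_factor_sd, size=(n_b, n_m, n_r))
        eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_metabolites, n_m, n_r))
        # (metabolite, month, replicate)
        factor = eta[:, :, None] + zeta                   # block x month x rep
        x = (baselines[:, None, None]
             + scale * (amps[block_idx, None, None] * season[None, :, None])
             + loadings[block_idx, None, None] * factor[block_idx]
             + eps)
        x = np.clip(x, 0.01, None)     # abundances are nonnegative
        index = pd.MultiIndex.from_product(
            [months, [state], range(1, n_r + 1)],
            names=["month", "state", "replicate"])
        values = x.reshape(cfg.n_metabolites, n_m * n_r).T
        frames.append(pd.DataFrame(values, index=index, columns=names))

    meta = pd.DataFrame(
        {"compound_class": [cfg.block_classes[b] for b in block_idx],
         "block": block_idx},
        index=pd.Index(names, name="metabolite"))
    table = AbundanceTable(pd.concat(frames), meta)

    # traits: binomial counts of surviving / germinating seeds out of 50
    p_surv = _survival_probabilities(cfg, eta_shared)
    p_germ = _germination_probabilities(cfg, eta_shared)
    rows = []
    for trait, probs in (("germination", p_germ), ("survival", p_surv)):
        counts = rng.binomial(TRAIT_BATCH_SIZE, probs[:, None], size=(n_m, n_r))
        for mi, m in enumerate(months):
            for k in range(n_r):
                rows.append((m, trait, k + 1, int(counts[mi, k])))
    traits = TraitSeries(pd.DataFrame(
        rows, columns=["month", "trait", "replicate", "successes"]))

    signs = {}
    for trait in TRAITS:
        for b, c in enumerate(cfg.trait_couplings[trait]):
            signs[(trait, b)] = "+" if c > 0 else "-" if c < 0 else "0"
    seasonal_means = pd.DataFrame(
        season[:, None] * amps[None, :], index=pd.Index(months, name="month"),
        columns=[f"block_{b}" for b in range(n_b)])
    truth = GroundTruth(dict(block_of), signs, seasonal_means)
    return table, traits, truth


def simulate_null_dataset(cfg: SimulationConfig) -> AbundanceTable:
    """Structure-free control: mutually independent Gaussian metabolites.

    All loadings, seasonal amplitudes and trait couplings are forced to
    zero, so every pairwise correlation in the output is a null case; used
    to check that the FDR of the edge-selection step is controlled.
    """
    import dataclasses
    nb = cfg.n_blocks
    null_cfg = dataclasses.replace(
        cfg,
        block_sizes=list(cfg.block_sizes),
        block_loadings=[0.0] * nb,
        seasonal_amplitude=[0.0] * nb,
        trait_couplings={t: [0.0] * nb for t in TRAITS},
    )
    table, _, _ = simulate_dataset(null_cfg)
    return table


def write_fixture(dataset: tuple[AbundanceTable, TraitSeries, GroundTruth],
                  outdir: str | Path) -> dict[str, Path]:
    """Write abundance.csv, traits.csv, metabolites.csv and truth.json.

    The CSVs round-trip losslessly through the readers in
    :mod:`seasonet.tables`.
    """
    table, traits, truth = dataset
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.csv",
        "traits": outdir / "traits.csv",
        "metabolite_meta": outdir / "metabolites.csv",
        "truth": outdir / "truth.json",
    }
    write_abundance_csv(table, paths["abundance"])
    write_traits_csv(traits, paths["traits"])
    write_metabolite_meta_csv(table, paths["metabolite_meta"])
    write_ground_truth_json(truth, paths["truth"])
    return paths


def read_fixture(outdir: str | Path) -> tuple[AbundanceTable, TraitSeries]:
    outdir = Path(outdir)
    table = read_abundance_csv(outdir / "abundance.csv", outdir / "metabolites.csv")
    traits = read_traits_csv(outdir / "traits.csv")
    return table, traits
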
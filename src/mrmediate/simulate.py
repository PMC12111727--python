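"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates the statistical shape of public two-sample MR
inputs — per-SNP marginal effects with sampling noise, block LD, a
quantitative exposure protein X, a quantitative protein-ratio mediator R
and a binary (log-odds scale) disease outcome Y — under the DAG

    X --beta1--> R --beta2--> Y,   X --direct--> Y,

so that the IVW estimands of the two-step pipeline equal (beta1_true,
beta2_true, total_true = direct_true + beta1_true * beta2_true) by
construction.

Model: each trait has a vector of *joint* per-SNP effects; marginal
effects are the joint effects mixed through the LD correlation matrix
(marginal = R_ld @ joint).  The observed beta of SNP j is drawn as
Normal(marginal_j, se_j) with se_j = s / sqrt(2 n maf_j (1 - maf_j)),
where s = 1 for a quantitative trait and s = 1/sqrt(phi (1-phi)) for a
binary outcome with case fraction phi (a liability-scale approximation of
the log-odds SE in a case-control GWAS).  Noise draws are independent per
trait, enforcing the disjoint-cohort (two-sample) assumption.  Everything
is deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.linalg import toeplitz

from .instruments import LDMatrix
from .sumstats import AssocRecord, SumStats, VariantKey

# non-palindromic allele pairs cycled deterministically along the panel
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

_TRAIT_CODES = {"X": 1, "R": 2, "Y": 3}


@dataclass
class SimTruth:
    """Ground truth of one simulated mediation scenario."""

    seed: int
    n_snps: int
    maf: np.ndarray
    ld_spec: tuple[int, float]  # (block_size, rho)
    exposure_effects: np.ndarray  # joint effects on X
    mediator_own_effects: np.ndarray  # joint direct effects on R
    outcome_own_effects: np.ndarray  # joint direct effects on Y (log-odds)
    beta1_true: float
    beta2_true: float
    direct_true: float
    n_exp: int
    n_med: int
    n_out: int
    case_fraction: float
    snps: list[str]
    chrom: str
    pos: np.ndarray
    ld: LDMatrix
    decoy_effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_true(self) -> float:
        """Total X -> Y effect, direct + beta1 * beta2 by construction."""
        return self.direct_true + self.beta1_true * self.beta2_true


@dataclass
class MediationScenario:
    """Generated summary statistics for one mediation scenario."""

    x: SumStats
    r: SumStats
    y: SumStats
    decoys: list[SumStats]
    ld: LDMatrix
    truth: SimTruth


@dataclass
class ColocScenario:
    """Two traits over one LD region with known causal variants."""

    trait1: SumStats
    trait2: SumStats
    ld: LDMatrix
    causal1: str
    causal2: str


def make_ld(
    n_snps: int,
    block_size: int,
    rho: float,
    snps: Optional[list[str]] = None,
) -> LDMatrix:
    """Block-diagonal AR(1) correlation: within a block, r between SNPs i
    and j is rho^|i-j|; zero across blocks.  Positive semidefinite by
    construction."""
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if block_size < 1 or n_snps < 1:
        raise ValueError("n_snps and block_size must be >= 1")
    r = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        b = stop - start
        r[start:stop, start:stop] = toeplitz(rho ** np.arange(b))
    if snps is None:
        snps = [f"rs{i + 1:06d}" for i in range(n_snps)]
    return LDMatrix(snps, r)


def _se_vector(n: int, maf: np.ndarray, scale: float) -> np.ndarray:
    return scale / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _build_sumstats(
    trait_id: str,
    trait_type: str,
    truth: SimTruth,
    joint: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> SumStats:
    scale = (
        1.0
        if trait_type == "quantitative"
        else 1.0 / np.sqrt(truth.case_fraction * (1.0 - truth.case_fraction))
    )
    se = _se_vector(n, truth.maf, scale)
    marginal = truth.ld.r @ joint
    beta = marginal + rng.normal(0.0, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)
    records = []
    for j, rsid in enumerate(truth.snps):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        records.append(
            AssocRecord(
                key=VariantKey(rsid, truth.chrom, int(truth.pos[j])),
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pval[j]),
                eaf=float(truth.maf[j]),
                n=n,
            )
        )
    return SumStats(trait_id, trait_type, records)


def _joint_effects(truth: SimTruth, trait: str) -> tuple[np.ndarray, int, str]:
    alpha = truth.exposure_effects
    gamma = truth.mediator_own_effects
    delta = truth.outcome_own_effects
    if trait == "X":
        return alpha, truth.n_exp, "quantitative"
    if trait == "R":
        return gamma + truth.beta1_true * alpha, truth.n_med, "quantitative"
    if trait == "Y":
        joint = (
            truth.total_true * alpha + truth.beta2_true * gamma + delta
        )
        return joint, truth.n_out, "binary"
    raise ValueError(f"trait must be X, R or Y, got {trait!r}")


def simulate_trait_sumstats(truth: SimTruth, trait: str) -> SumStats:
    """Summary statistics of one trait (X, R or Y) implied by the truth.

    Deterministic under ``truth.seed``; each trait uses an independent
    noise stream (disjoint cohorts)."""
    joint, n, trait_type = _joint_effects(truth, trait)
    rng = np.random.default_rng([truth.seed, _TRAIT_CODES[trait]])
    names = {"X": "exposure_protein", "R": "ratio_mediator", "Y": "outcome"}
    return _build_sumstats(names[trait], trait_type, truth, joint, n, rng)


def _planted_effects(
    rng: np.random.Generator,
    n_snps: int,
    block_size: int,
    blocks: range,
    low: float,
    high: float,
) -> np.ndarray:
    """Random-sign effects of magnitude U(low, high) at block centers."""
    eff = np.zeros(n_snps)
    for b in blocks:
        idx = b * block_size + block_size // 2
        eff[idx] = rng.uniform(low, high) * rng.choice([-1.0, 1.0])
    return eff


def simulate_mediation_scenario(
    beta1: float = -0.084,
    beta2: float = 0.159,
    direct: float = -0.1296,
    seed: int = 0,
    n_snps: int = 500,
    block_size: int = 10,
    rho: float = 0.5,
    n_x_instruments: int = 20,
    n_r_instruments: int = 20,
    n_y_instruments: int = 5,
    n_decoys: int = 0,
    decoy_instruments: int = 3,
    n_exp: int = 50_000,
    n_med: int = 50_000,
    n_out: int = 50_000,
    case_fraction: float = 0.2,
    effect_range: tuple[float, float] = (0.15, 0.25),
) -> MediationScenario:
    """Generate a full two-sample mediation scenario.

    Instruments for X, R, Y and each decoy mediator live at the centers of
    disjoint LD blocks; instrument magnitudes are drawn from
    ``effect_range`` with random signs (strong pQTL-like instruments).
    Decoy mediators have their own instruments but no X -> decoy path and
    no effect on Y, providing specificity targets for the screen.  The
    default triple (beta1, beta2, direct) reproduces a protective exposure
    whose mediated path acts with the total effect."""
    n_blocks = n_snps // block_size
    need = n_x_instruments + n_r_instruments + n_y_instruments + n_decoys * decoy_instruments
    if need > n_blocks:
        raise ValueError(
            f"{need} instrument blocks requested but only {n_blocks} available"
        )
    rng = np.random.default_rng([seed, 0])
    maf = rng.uniform(0.05, 0.5, size=n_snps)
    alpha = _planted_effects(
        rng, n_snps, block_size, range(0, n_x_instruments), *effect_range
    )
    gamma = _planted_effects(
        rng,
        n_snps,
        block_size,
        range(n_x_instruments, n_x_instruments + n_r_instruments),
        *effect_range,
    )
    y_start = n_x_instruments + n_r_instruments
    delta = _planted_effects(
        rng, n_snps, block_size, range(y_start, y_start + n_y_instruments), 0.10, 0.18
    )
    snps = [f"rs{i + 1:06d}" for i in range(n_snps)]
    pos = np.arange(n_snps, dtype=int) * 10_000 + 1
    ld = make_ld(n_snps, block_size, rho, snps=snps)
    decoy_effects = {}
    d_start = y_start + n_y_instruments
    for d in range(n_decoys):
        blocks = range(
            d_start + d * decoy_instruments, d_start + (d + 1) * decoy_instruments
        )
        decoy_effects[f"decoy_ratio_{d + 1}"] = _planted_effects(
            rng, n_snps, block_size, blocks, *effect_range
        )
    truth = SimTruth(
        seed=seed,
        n_snps=n_snps,
        maf=maf,
        ld_spec=(block_size, rho),
        exposure_effects=alpha,
        mediator_own_effects=gamma,
        outcome_own_effects=delta,
        beta1_true=beta1,
        beta2_true=beta2,
        direct_true=direct,
        n_exp=n_exp,
        n_med=n_med,
        n_out=n_out,
        case_fraction=case_fraction,
        snps=snps,
        chrom="1",
        pos=pos,
        ld=ld,
        decoy_effects=decoy_effects,
    )
    x = simulate_trait_sumstats(truth, "X")
    r = simulate_trait_sumstats(truth, "R")
    y = simulate_trait_sumstats(truth, "Y")
    decoys = []
    for d, (name, eff) in enumerate(decoy_effects.items()):
        drng = np.random.default_rng([seed, 10 + d])
        decoys.append(
            _build_sumstats(name, "quantitative", truth, eff, n_med, drng)
        )
    return MediationScenario(x=x, r=r, y=y, decoys=decoys, ld=ld, truth=truth)


def simulate_coloc_scenario(
    mode: str = "shared",
    region_size: int = 200,
    z_strength: float = 8.0,
    seed: int = 0,
    rho: float = 0.8,
    block_size: int = 50,
    n: int = 20_000,
) -> ColocScenario:
    """One LD region with a single causal variant per trait.

    ``shared`` places one causal variant affecting both traits; ``distinct``
    places two causal variants in different LD blocks (hence uncorrelated),
    one per trait.  The causal variant's marginal z-score is
    ``z_strength``."""
    if mode not in ("shared", "distinct"):
        raise ValueError(f"mode must be 'shared' or 'distinct', got {mode!r}")
    if region_size < 10:
        raise ValueError("region_size must be >= 10")
    rng = np.random.default_rng([seed, 20])
    maf = rng.uniform(0.1, 0.5, size=region_size)
    snps = [f"rs{i + 1:06d}" for i in range(region_size)]
    pos = np.arange(region_size, dtype=int) * 2_000 + 1
    ld = make_ld(region_size, block_size, rho, snps=snps)
    se = _se_vector(n, maf, 1.0)
    c1 = region_size // 4
    c2 = c1 if mode == "shared" else 3 * region_size // 4

    def _trait(name: str, causal: int, code: int) -> SumStats:
        joint = np.zeros(region_size)
        joint[causal] = z_strength * se[causal]
        marginal = ld.r @ joint
        trng = np.random.default_rng([seed, code])
        beta = marginal + trng.normal(0.0, se)
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)
        records = [
            AssocRecord(
                key=VariantKey(snps[j], "1", int(pos[j])),
                effect_allele=_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0],
                other_allele=_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1],
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pval[j]),
                eaf=float(maf[j]),
                n=n,
            )
            for j in range(region_size)
        ]
        return SumStats(name, "quantitative", records)

    return ColocScenario(
        trait1=_trait("region_trait_1", c1, 21),
        trait2=_trait("region_trait_2", c2, 22),
        ld=ld,
        causal1=snps[c1],
        causal2=snps[c2],
    )


def simulate_null_screen_panel(
    n_exposures: int = 200,
    n_instruments: int = 6,
    n_null_snps: int = 4,
    n_exp: int = 20_000,
    n_out: int = 22_347,
    case_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SumStats], SumStats, LDMatrix]:
    """Panel of exposures with real instruments but no effect on the outcome.

    Each exposure owns its own uncorrelated SNPs (``n_instruments`` strong
    ones plus ``n_null_snps`` null fillers); the binary outcome covers the
    union of all SNPs with pure sampling noise.  Used to check the type-I
    error of the forward screen.  The LD reference is returned empty (all
    pairs uncorrelated)."""
    master = np.random.default_rng([seed, 30])
    exposures = []
    out_records = []
    out_rng = np.random.default_rng([seed, 31])
    s_bin = 1.0 / np.sqrt(case_fraction * (1.0 - case_fraction))
    for i in range(n_exposures):
        rng = np.random.default_rng([seed, 100 + i])
        k = n_instruments + n_null_snps
        maf = master.uniform(0.1, 0.4, size=k)
        se_x = _se_vector(n_exp, maf, 1.0)
        joint = np.zeros(k)
        joint[:n_instruments] = master.uniform(0.10, 0.16, size=n_instruments) * (
            master.choice([-1.0, 1.0], size=n_instruments)
        )
        beta = joint + rng.normal(0.0, se_x)
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se_x), 1e-300, 1.0)
        records = []
        for j in range(k):
            rsid = f"rs{i:04d}x{j:02d}"
            ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
            key = VariantKey(rsid, str(i + 1), j * 10_000 + 1)
            records.append(
                AssocRecord(key, ea, oa, float(beta[j]), float(se_x[j]),
                            float(pval[j]), float(maf[j]), n_exp)
            )
            se_y = float(s_bin / np.sqrt(2.0 * n_out * maf[j] * (1.0 - maf[j])))
            by = float(out_rng.normal(0.0, se_y))
            py = float(np.clip(2.0 * stats.norm.sf(abs(by) / se_y), 1e-300, 1.0))
            out_records.append(
                AssocRecord(key, ea, oa, by, se_y, py, float(maf[j]), n_out)
            )
        exposures.append(SumStats(f"null_exposure_{i}", "quantitative", records))
    outcome = SumStats("outcome", "binary", out_records)
    ld = LDMatrix([], np.zeros((0, 0)))
    return exposures, outcome, ld
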
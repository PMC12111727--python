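"""Bayesian colocalization of two traits over a shared region.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from
the marginal beta and SE under a Gaussian effect prior with standard
deviation ``prior_sd``.  Assuming at most one causal variant per trait in
the region, the posterior mass is split across five hypotheses:

* H0 - no association with either trait;
* H1 / H2 - association with trait 1 / trait 2 only;
* H3 - both traits associated, distinct causal variants;
* H4 - both traits associated, one shared causal variant.

All mixture arithmetic is done in log space with log-sum-exp.  PPH4 above
0.75 is conventionally read as compelling evidence for a shared causal
variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumStats, harmonize

#: default effect-prior SD by trait type (quantitative traits in SD units,
#: binary traits on the log-odds scale)
PRIOR_SD = {"quantitative": 0.20, "binary": 0.15}

#: posterior threshold for declaring colocalization
PPH4_THRESHOLD = 0.75


@dataclass
class ColocInput:
    """Aligned per-SNP effects of two traits over one region."""

    snps: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    type1: str = "quantitative"
    type2: str = "quantitative"
    prior_sd1: Optional[float] = None
    prior_sd2: Optional[float] = None

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, float)
        self.se1 = np.asarray(self.se1, float)
        self.beta2 = np.asarray(self.beta2, float)
        self.se2 = np.asarray(self.se2, float)
        k = len(self.snps)
        if k < 1:
            raise ValueError("need at least one SNP")
        for name in ("beta1", "se1", "beta2", "se2"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("all SEs must be positive")
        if self.prior_sd1 is None:
            self.prior_sd1 = PRIOR_SD[self.type1]
        if self.prior_sd2 is None:
            self.prior_sd2 = PRIOR_SD[self.type2]


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snp: int
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        total = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1, got {total}")

    def colocalized(self, threshold: float = PPH4_THRESHOLD) -> bool:
        return self.pph4 > threshold


def log_abf(beta, se, prior_sd: float):
    """Log Wakefield approximate Bayes factor for association.

    With V = se^2, W = prior_sd^2 and z = beta/se:
    ``0.5*ln(V/(V+W)) + 0.5*z^2*W/(V+W)``.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if not prior_sd > 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)
    return float(out) if out.ndim == 0 else out


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), floored at -inf when non-positive."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalize(
    inp: ColocInput,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior probabilities PPH0-PPH4 from per-SNP log ABFs.

    ``p1``/``p2`` are the per-SNP prior probabilities of association with
    each trait alone and ``p12`` with both; ``p1 + p2 + p12`` must be < 1.
    H3's weight sums ABF products over ordered distinct SNP pairs, computed
    as a log-difference; it is 0 for a single-SNP region.
    """
    if not (0 < p1 and 0 < p2 and 0 < p12 and p1 + p2 + p12 < 1):
        raise ValueError("priors must be positive with p1 + p2 + p12 < 1")
    l1 = log_abf(inp.beta1, inp.se1, inp.prior_sd1)
    l2 = log_abf(inp.beta2, inp.se2, inp.prior_sd2)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lw = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            (np.log(p1) + np.log(p2) + _logdiff(s1 + s2, s12))
            if len(inp.snps) > 1
            else -np.inf,
            np.log(p12) + s12,
        ]
    )
    post = np.exp(lw - logsumexp(lw))
    post /= post.sum()
    return ColocResult(
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        n_snp=len(inp.snps),
        p1=p1,
        p2=p2,
        p12=p12,
    )


def coloc_region(
    exposure: SumStats,
    outcome: SumStats,
    lead: Optional[str] = None,
    window_kb: float = 500.0,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: Optional[float] = None,
    prior_sd2: Optional[float] = None,
) -> ColocResult:
    """Colocalize the region around a lead variant of the exposure.

    ``lead`` defaults to the exposure's smallest-p variant.  Variants of the
    exposure within ``window_kb`` of the lead (same chromosome) are
    intersected with the outcome, harmonized onto a shared allele frame,
    and passed to :func:`colocalize` with trait-type default priors.
    Raises when fewer than two shared variants remain.
    """
    rmap = exposure.record_map()
    if lead is None:
        lead = min(exposure.records, key=lambda r: (r.pval, r.key.rsid)).key.rsid
    if lead not in rmap:
        raise KeyError(f"lead variant {lead!r} not in exposure {exposure.trait_id!r}")
    center = rmap[lead].key
    window_bp = window_kb * 1000.0
    region = [
        r.key.rsid
        for r in exposure.records
        if r.key.chrom == center.chrom and abs(r.key.pos - center.pos) <= window_bp
    ]
    h = harmonize(exposure.subset(region), outcome)
    if len(h) < 2:
        raise ValueError(
            f"fewer than 2 shared variants around {lead!r} "
            f"({exposure.trait_id!r} vs {outcome.trait_id!r})"
        )
    inp = ColocInput(
        snps=h.rsids,
        beta1=h.beta_exp,
        se1=h.se_exp,
        beta2=h.beta_out,
        se2=h.se_out,
        type1=exposure.trait_type,
        type2=outcome.trait_type,
        prior_sd1=prior_sd1,
        prior_sd2=prior_sd2,
    )
    return colocalize(inp, p1=p1, p2=p2, p12=p12)
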
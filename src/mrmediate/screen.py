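"""Screening cascade: forward MR, reverse-causality exclusion, mediator
screening with FDR correction and colocalization, and two-step mediation.

The cascade mirrors the standard protein -> protein-ratio -> disease
two-step MR design:

1. forward MR of every exposure on the outcome, keeping P_IVW < alpha;
2. reverse MR (outcome as exposure) to discard candidates with evidence of
   reverse causation;
3. for each surviving exposure, bidirectional MR against a panel of
   candidate mediators, keeping unidirectional exposure -> mediator links;
4. mediator -> outcome MR with Benjamini-Hochberg FDR within each
   exposure's mediator family, plus regional colocalization of each
   surviving mediator with the outcome;
5. the two-step mediated proportion 100 * (beta1 * beta2) / beta, where
   beta1 is the exposure -> mediator IVW estimate, beta2 the
   mediator -> outcome IVW estimate, and beta the total exposure -> outcome
   IVW estimate.

Candidates whose MR-Egger intercept signals directional pleiotropy
(p < alpha) are flagged and re-estimated after MR-PRESSO outlier removal
rather than silently dropped; candidates without compelling colocalization
(PPH4 <= threshold) are retained but labelled, since a causal relationship
cannot be ruled out for them.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .coloc import ColocResult, coloc_region
from .instruments import LDMatrix, select_instruments
from .mr import MRResult, egger, ivw, presso
from .sumstats import HarmonizedSet, SumStats, harmonize

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Thresholds and knobs of the screening cascade (defaults as used
    throughout: instrument p < 1e-5, clumping r2 < 0.001 within 10,000 kb,
    F > 10, alpha = 0.05, FDR 0.05, PPH4 > 0.75, at least 2 instruments)."""

    p_instrument: float = 1e-5
    r2: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    pph4_threshold: float = 0.75
    min_snps: int = 2
    ivw_mode: str = "mre"
    presso_n_sim: int = 1000
    coloc_window_kb: float = 500.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CausalCandidate:
    """One exposure-outcome pair surviving (part of) the cascade.

    For mediator candidates, ``upstream`` carries the original
    exposure -> mediator estimate (beta1) and ``upstream_reverse`` the
    mediator -> original-exposure reverse check.
    """

    exposure_id: str
    outcome_id: str
    forward: MRResult
    reverse: Optional[MRResult] = None
    unidirectional: Optional[bool] = None
    pleiotropy_flag: bool = False
    heterogeneity_flag: bool = False
    adj_p: Optional[float] = None
    coloc: Optional[ColocResult] = None
    upstream: Optional[MRResult] = None
    upstream_reverse: Optional[MRResult] = None
    n_outliers_removed: int = 0


@dataclass
class MediationResult:
    """Two-step mediation decomposition for one exposure/mediator/outcome
    triple.  ``proportion`` is the mediated proportion in percent,
    100 * (beta1 * beta2) / total_beta; it is signed, negative meaning the
    mediated path acts against the total effect."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    beta2: float
    total_beta: float
    indirect: float
    proportion: Optional[float]
    direction_consistent: Optional[bool]


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mediation(
    beta1: float,
    beta2: float,
    total_beta: float,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Mediated proportion of the two-step decomposition.

    ``indirect = beta1 * beta2``; ``proportion = 100 * indirect /
    total_beta`` percent (undefined and flagged when the total effect is
    zero).  ``direction_consistent`` states whether the mediated path acts
    in the same direction as the total effect; it is defined only when
    both are nonzero.
    """
    indirect = beta1 * beta2
    if total_beta == 0:
        logger.warning("mediation: zero total effect, proportion undefined")
        proportion = None
    else:
        proportion = 100.0 * indirect / total_beta
    direction = (
        (indirect > 0) == (total_beta > 0)
        if indirect != 0 and total_beta != 0
        else None
    )
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=beta1,
        beta2=beta2,
        total_beta=total_beta,
        indirect=indirect,
        proportion=proportion,
        direction_consistent=direction,
    )


def _derived_seed(cfg_seed: int, label: str) -> int:
    """Deterministic per-pair seed below 2^31, independent of list order."""
    return (cfg_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def _fit_pair(
    exp_sub: SumStats,
    outcome: SumStats,
    cfg: ScreenConfig,
) -> Optional[CausalCandidate]:
    """IVW + Egger on a harmonized pair, with PRESSO correction when the
    Egger intercept flags pleiotropy.  Returns None when fewer than
    ``cfg.min_snps`` instruments survive harmonization."""
    h = harmonize(exp_sub, outcome)
    if len(h) < cfg.min_snps:
        return None
    fw = ivw(h, cfg.ivw_mode)
    eg = egger(h) if len(h) >= 3 else None
    pleio = eg is not None and eg.egger_intercept_pval < cfg.alpha
    n_removed = 0
    if pleio and len(h) >= 4:
        seed = _derived_seed(cfg.seed, f"{exp_sub.trait_id}->{outcome.trait_id}")
        pr = presso(h, n_sim=cfg.presso_n_sim, alpha=cfg.alpha, seed=seed)
        if pr.outliers and len(pr.outliers) < len(h):
            h = h.drop(pr.outliers)
            n_removed = len(pr.outliers)
            fw = ivw(h, cfg.ivw_mode)
            eg = egger(h) if len(h) >= 3 else None
            pleio = eg is not None and eg.egger_intercept_pval < cfg.alpha
    cand = CausalCandidate(
        exposure_id=exp_sub.trait_id,
        outcome_id=outcome.trait_id,
        forward=fw,
        pleiotropy_flag=pleio,
        heterogeneity_flag=fw.q_pval is not None and fw.q_pval < cfg.alpha,
        n_outliers_removed=n_removed,
    )
    if eg is not None:
        cand.forward.egger_intercept = eg.egger_intercept
        cand.forward.egger_intercept_se = eg.egger_intercept_se
        cand.forward.egger_intercept_pval = eg.egger_intercept_pval
    return cand


def forward_screen(
    exposures: Sequence[SumStats],
    outcome: SumStats,
    ld: LDMatrix,
    cfg: ScreenConfig,
    exclusions: Optional[dict[str, str]] = None,
) -> list[CausalCandidate]:
    """Forward MR of every exposure on the outcome.

    Per exposure: instrument selection, harmonization, IVW + Egger (+
    PRESSO correction when pleiotropy is flagged).  Only candidates with
    forward P_IVW < alpha are retained.  When a dict is passed as
    ``exclusions`` it is filled with exposure_id -> reason for every
    exposure that did not survive.
    """
    candidates = []
    for exposure in exposures:
        reason = None
        try:
            sel = select_instruments(
                exposure,
                ld,
                p_threshold=cfg.p_instrument,
                r2_threshold=cfg.r2,
                window_kb=cfg.window_kb,
                f_min=cfg.f_min,
            )
            if len(sel.kept) < cfg.min_snps:
                reason = "min_snps"
            else:
                cand = _fit_pair(exposure.subset(sel.kept), outcome, cfg)
                if cand is None:
                    reason = "min_snps"
                elif cand.forward.pval >= cfg.alpha:
                    reason = "not_significant"
                else:
                    candidates.append(cand)
        except ValueError as err:
            reason = f"failed: {err}"
            logger.warning("forward_screen: %s skipped (%s)", exposure.trait_id, err)
        if reason is not None:
            logger.info("forward_screen: %s excluded (%s)", exposure.trait_id, reason)
            if exclusions is not None:
                exclusions[exposure.trait_id] = reason
    return candidates


def reverse_screen(
    candidates: Sequence[CausalCandidate],
    outcome_as_exposure: SumStats,
    exposure_stats: Mapping[str, SumStats],
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> list[CausalCandidate]:
    """Reverse MR with roles swapped; sets ``reverse`` and
    ``unidirectional`` on every candidate.

    A candidate is unidirectional when its forward P_IVW < alpha and its
    reverse P_IVW is absent (no usable reverse instruments) or >= alpha;
    candidates with reverse P_IVW < alpha are thereby marked excluded.
    """
    sel = select_instruments(
        outcome_as_exposure,
        ld,
        p_threshold=cfg.p_instrument,
        r2_threshold=cfg.r2,
        window_kb=cfg.window_kb,
        f_min=cfg.f_min,
    )
    out_sub = (
        outcome_as_exposure.subset(sel.kept) if len(sel.kept) >= cfg.min_snps else None
    )
    if out_sub is None:
        logger.warning(
            "reverse_screen: %s has < %d instruments, reverse MR skipped",
            outcome_as_exposure.trait_id,
            cfg.min_snps,
        )
    out = []
    for cand in candidates:
        rev = None
        if out_sub is not None:
            try:
                h = harmonize(out_sub, exposure_stats[cand.exposure_id])
                if len(h) >= cfg.min_snps:
                    rev = ivw(h, cfg.ivw_mode)
            except (ValueError, KeyError) as err:
                logger.warning(
                    "reverse_screen: %s failed (%s)", cand.exposure_id, err
                )
        cand.reverse = rev
        cand.unidirectional = cand.forward.pval < cfg.alpha and (
            rev is None or rev.pval >= cfg.alpha
        )
        out.append(cand)
    return out


def mediator_screen(
    exposure: SumStats,
    mediators: Sequence[SumStats],
    outcome: SumStats,
    ld: LDMatrix,
    cfg: ScreenConfig,
    exclusions: Optional[dict[str, str]] = None,
) -> list[CausalCandidate]:
    """Screen candidate mediators of one exposure's effect on the outcome.

    Bidirectional MR exposure <-> mediator keeps unidirectional
    exposure -> mediator links; surviving mediators are tested against the
    outcome with BH FDR within this exposure's family (adjusted p <
    ``fdr_alpha``); each survivor is then colocalized with the outcome
    around its lead variant.  Returned candidates carry the mediator ->
    outcome MR as ``forward`` (beta2), the exposure -> mediator MR as
    ``upstream`` (beta1), the FDR-adjusted p and the coloc result.
    """

    def _exclude(med_id: str, reason: str) -> None:
        logger.info("mediator_screen: %s excluded (%s)", med_id, reason)
        if exclusions is not None:
            exclusions[med_id] = reason

    x_sel = select_instruments(
        exposure, ld, cfg.p_instrument, cfg.r2, cfg.window_kb, cfg.f_min
    )
    if len(x_sel.kept) < cfg.min_snps:
        logger.warning(
            "mediator_screen: exposure %s has < %d instruments", exposure.trait_id,
            cfg.min_snps,
        )
        return []
    x_sub = exposure.subset(x_sel.kept)

    stage: list[tuple[SumStats, MRResult, Optional[MRResult]]] = []
    for med in mediators:
        try:
            h_xm = harmonize(x_sub, med)
        except ValueError:
            _exclude(med.trait_id, "no_overlap")
            continue
        if len(h_xm) < cfg.min_snps:
            _exclude(med.trait_id, "min_snps")
            continue
        up = ivw(h_xm, cfg.ivw_mode)
        if up.pval >= cfg.alpha:
            _exclude(med.trait_id, "no_forward_effect")
            continue
        rev = None
        m_sel = select_instruments(
            med, ld, cfg.p_instrument, cfg.r2, cfg.window_kb, cfg.f_min
        )
        if len(m_sel.kept) >= cfg.min_snps:
            try:
                h_mx = harmonize(med.subset(m_sel.kept), exposure)
                if len(h_mx) >= cfg.min_snps:
                    rev = ivw(h_mx, cfg.ivw_mode)
            except ValueError:
                pass
        if rev is not None and rev.pval < cfg.alpha:
            _exclude(med.trait_id, "bidirectional")
            continue
        stage.append((med, up, rev))

    family: list[CausalCandidate] = []
    family_meds: list[SumStats] = []
    for med, up, rev in stage:
        m_sel = select_instruments(
            med, ld, cfg.p_instrument, cfg.r2, cfg.window_kb, cfg.f_min
        )
        if len(m_sel.kept) < cfg.min_snps:
            _exclude(med.trait_id, "min_snps_mediator")
            continue
        try:
            cand = _fit_pair(med.subset(m_sel.kept), outcome, cfg)
        except ValueError as err:
            _exclude(med.trait_id, f"failed: {err}")
            continue
        if cand is None:
            _exclude(med.trait_id, "min_snps_mediator")
            continue
        cand.upstream = up
        cand.upstream_reverse = rev
        cand.unidirectional = True
        family.append(cand)
        family_meds.append(med)

    if not family:
        return []
    adj = bh_fdr([c.forward.pval for c in family])
    survivors = []
    for cand, med, a in zip(family, family_meds, adj):
        cand.adj_p = float(a)
        if a >= cfg.fdr_alpha:
            _exclude(cand.exposure_id, "fdr")
            continue
        try:
            cand.coloc = coloc_region(
                med, outcome, window_kb=cfg.coloc_window_kb
            )
        except ValueError as err:
            logger.warning("mediator_screen: coloc failed for %s (%s)",
                           med.trait_id, err)
        survivors.append(cand)
    return survivors


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineData:
    """Input bundle: an exposure panel, a mediator panel, one outcome trait
    and the LD reference."""

    exposures: list[SumStats]
    mediators: list[SumStats]
    outcome: SumStats
    ld: LDMatrix


@dataclass
class PipelineResult:
    """Report bundle: the three result tables plus the run manifest."""

    candidates: list[CausalCandidate]
    mediator_candidates: dict[str, list[CausalCandidate]]
    mediations: list[MediationResult]
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        """Write table1/2/3 TSVs and the YAML manifest into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1_exposure_outcome.tsv", sep="\t", index=False)
        self.table2.to_csv(outdir / "table2_reverse.tsv", sep="\t", index=False)
        self.table3.to_csv(outdir / "table3_mediation.tsv", sep="\t", index=False)
        with (outdir / "manifest.yaml").open("w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def _fmt_or(res: MRResult) -> str:
    return "%.3f(%.3f-%.3f)" % (res.or_, res.ci_low, res.ci_high)


def _fmt_p(p: Optional[float]) -> str:
    return "NA" if p is None else "%.4g" % p


def run_pipeline(data: PipelineData, cfg: ScreenConfig) -> PipelineResult:
    """Execute the full cascade and assemble the report tables.

    Table 1: exposure -> outcome bidirectional MR for retained exposures;
    Table 2: candidates excluded for reverse causation (outcome as
    exposure); Table 3: mediation decompositions for every surviving
    (exposure, mediator) pair.  Empty gates yield empty tables, never a
    crash; all gate counts are recorded in the manifest.
    """
    counts = {"exposures_in": len(data.exposures), "mediators_in": len(data.mediators)}
    exclusions: dict[str, str] = {}

    fw = forward_screen(data.exposures, data.outcome, data.ld, cfg, exclusions)
    counts["forward_significant"] = len(fw)

    exp_map = {s.trait_id: s for s in data.exposures}
    cands = reverse_screen(fw, data.outcome, exp_map, data.ld, cfg)
    surviving = [c for c in cands if c.unidirectional]
    reverse_excluded = [c for c in cands if not c.unidirectional]
    counts["reverse_excluded"] = len(reverse_excluded)
    counts["unidirectional"] = len(surviving)

    t1_rows = []
    for c in cands:
        t1_rows.append(
            {
                "Exposure": c.exposure_id,
                "Outcome": c.outcome_id,
                "SNPs": c.forward.n_snp,
                "OR(95%CI)": _fmt_or(c.forward),
                "P_IVW": _fmt_p(c.forward.pval),
                "P_Heterogeneity": _fmt_p(c.forward.q_pval),
                "P_Pleiotropy": _fmt_p(c.forward.egger_intercept_pval),
                "Reverse_MR_P_IVW": _fmt_p(c.reverse.pval if c.reverse else None),
            }
        )
    t1_cols = [
        "Exposure", "Outcome", "SNPs", "OR(95%CI)", "P_IVW",
        "P_Heterogeneity", "P_Pleiotropy", "Reverse_MR_P_IVW",
    ]
    table1 = pd.DataFrame(t1_rows, columns=t1_cols)

    t2_rows = []
    for c in reverse_excluded:
        if c.reverse is None:
            continue
        t2_rows.append(
            {
                "Exposure": c.outcome_id,
                "Outcome": c.exposure_id,
                "SNPs": c.reverse.n_snp,
                "OR(95%CI)": _fmt_or(c.reverse),
                "P_IVW": _fmt_p(c.reverse.pval),
            }
        )
    table2 = pd.DataFrame(
        t2_rows, columns=["Exposure", "Outcome", "SNPs", "OR(95%CI)", "P_IVW"]
    )

    med_cands: dict[str, list[CausalCandidate]] = {}
    mediations: list[MediationResult] = []
    t3_rows = []
    for c in surviving:
        mexcl: dict[str, str] = {}
        mc = mediator_screen(
            exp_map[c.exposure_id], data.mediators, data.outcome, data.ld, cfg, mexcl
        )
        med_cands[c.exposure_id] = mc
        for cand in mc:
            med = mediation(
                beta1=cand.upstream.beta,
                beta2=cand.forward.beta,
                total_beta=c.forward.beta,
                exposure_id=c.exposure_id,
                mediator_id=cand.exposure_id,
                outcome_id=c.outcome_id,
            )
            mediations.append(med)
            coloc_ok = (
                cand.coloc is not None
                and cand.coloc.colocalized(cfg.pph4_threshold)
            )
            t3_rows.append(
                {
                    "Exposure": med.exposure_id,
                    "Mediator": med.mediator_id,
                    "Outcome": med.outcome_id,
                    "Beta1": "%.3f" % med.beta1,
                    "Beta2": "%.3f" % med.beta2,
                    "TotalBeta": "%.3f" % med.total_beta,
                    "MediatedProportion": (
                        "NA" if med.proportion is None else "%.3f%%" % med.proportion
                    ),
                    "AdjustP_IVW": _fmt_p(cand.adj_p),
                    "PPH4": (
                        "NA" if cand.coloc is None else "%.3f" % cand.coloc.pph4
                    ),
                    "Colocalized": "yes" if coloc_ok else "not_established",
                }
            )
    counts["mediation_pairs"] = len(mediations)
    t3_cols = [
        "Exposure", "Mediator", "Outcome", "Beta1", "Beta2", "TotalBeta",
        "MediatedProportion", "AdjustP_IVW", "PPH4", "Colocalized",
    ]
    table3 = pd.DataFrame(t3_rows, columns=t3_cols)

    manifest = {
        "tool_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "gate_counts": counts,
        "exclusions": exclusions,
    }
    return PipelineResult(
        candidates=cands,
        mediator_candidates=med_cands,
        mediations=mediations,
        table1=table1,
        table2=table2,
        table3=table3,
        manifest=manifest,
    )
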
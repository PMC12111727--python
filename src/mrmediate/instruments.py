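"""Instrument-variable selection for two-sample MR.

Three sequential filters produce the instrument set for an exposure:

1. genome-wide significance (``pval`` strictly below a threshold,
   default 1e-5);
2. greedy LD clumping: keep the most significant remaining variant, drop
   every remaining variant on the same chromosome within the distance window
   whose squared correlation with it reaches the r2 threshold (defaults
   r2 < 0.001 within +/-10,000 kb);
3. per-SNP instrument strength F = beta^2 / SE^2, keeping F strictly
   greater than 10 (the conventional weak-instrument cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise correlation (r, not r^2) between variants.

    Variants absent from the matrix are treated as uncorrelated (r = 0)
    by consumers; an empty matrix therefore encodes "no LD information".
    """

    snps: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snps)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if k:
            if not np.allclose(self.r, self.r.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
                raise ValueError("LD matrix diagonal must be 1")
            if np.any(np.abs(self.r) > 1 + 1e-9):
                raise ValueError("LD correlations must satisfy |r| <= 1")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def __len__(self) -> int:
        return len(self.snps)

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants; 0 when either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib]) ** 2

    def to_file(self, path: str | Path) -> None:
        """Write as a square TSV with rsid header row and column."""
        df = pd.DataFrame(self.r, index=self.snps, columns=self.snps)
        df.to_csv(path, sep="\t", index_label="rsid", float_format="%.10g")


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD matrix from a square TSV (rsid header row/column) or a
    long-format triplet file with columns (rsid_a, rsid_b, r)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and cols[:2] == ["rsid_a", "rsid_b"]:
        snps = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        idx = {s: i for i, s in enumerate(snps)}
        r = np.eye(len(snps))
        for a, b, val in df.itertuples(index=False):
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = float(val)
        return LDMatrix(snps, r)
    df = df.set_index(df.columns[0])
    return LDMatrix([str(s) for s in df.index], df.to_numpy(float))


@dataclass
class InstrumentSelection:
    """Outcome of instrument selection with per-filter drop counts."""

    kept: list[str]
    dropped_p: int = 0
    dropped_ld: int = 0
    dropped_f: int = 0
    f_stats: dict[str, float] = field(default_factory=dict)


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = beta^2 / SE^2."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_significant(ss: SumStats, p_threshold: float = 1e-5) -> SumStats:
    """Records with pval strictly below ``p_threshold``."""
    kept = [r for r in ss.records if r.pval < p_threshold]
    return SumStats(ss.trait_id, ss.trait_type, kept)


def clump(
    ss: SumStats,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> InstrumentSelection:
    """Greedy LD clumping.

    Records are ordered by ascending pval (ties broken by rsid); the best
    remaining record is kept and every remaining record on the same
    chromosome within ``window_kb`` (center-to-center) whose r^2 with it
    reaches ``r2_threshold`` is dropped.  Records on different chromosomes
    are never clumped against each other.  The result is invariant to the
    input row order.
    """
    if len(ld) == 0 and len(ss) > 1:
        logger.debug("clump: empty LD matrix, all variants treated as uncorrelated")
    missing = [r.key.rsid for r in ss.records if len(ld) and r.key.rsid not in ld._index]
    if missing:
        logger.warning(
            "clump: %d variants absent from the LD matrix, assumed uncorrelated",
            len(missing),
        )
    window_bp = window_kb * 1000.0
    active = sorted(ss.records, key=lambda r: (r.pval, r.key.rsid))
    kept: list[str] = []
    dropped_ld = 0
    while active:
        index = active.pop(0)
        kept.append(index.key.rsid)
        survivors = []
        for rec in active:
            if (
                rec.key.chrom == index.key.chrom
                and abs(rec.key.pos - index.key.pos) <= window_bp
                and ld.r2(index.key.rsid, rec.key.rsid) >= r2_threshold
            ):
                dropped_ld += 1
            else:
                survivors.append(rec)
        active = survivors
    return InstrumentSelection(kept=kept, dropped_ld=dropped_ld)


def select_instruments(
    ss: SumStats,
    ld: LDMatrix,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    f_min: float = 10.0,
) -> InstrumentSelection:
    """Significance filter, then LD clumping, then the F > ``f_min`` filter.

    ``f_stats`` records the per-SNP F for every clump survivor, including
    those subsequently dropped as weak.
    """
    sig = filter_significant(ss, p_threshold)
    dropped_p = len(ss) - len(sig)
    if len(sig) == 0:
        return InstrumentSelection(kept=[], dropped_p=dropped_p)
    cl = clump(sig, ld, r2_threshold, window_kb)
    rmap = sig.record_map()
    f_stats = {rsid: f_statistic(rmap[rsid].beta, rmap[rsid].se) for rsid in cl.kept}
    kept = [rsid for rsid in cl.kept if f_stats[rsid] > f_min]
    return InstrumentSelection(
        kept=kept,
        dropped_p=dropped_p,
        dropped_ld=cl.dropped_ld,
        dropped_f=len(cl.kept) - len(kept),
        f_stats=f_stats,
    )
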
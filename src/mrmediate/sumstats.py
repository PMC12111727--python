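"""GWAS summary-statistics containers, delimited-text I/O, and allele harmonization.

The data model is intentionally minimal: one variant's marginal association
with one trait (:class:`AssocRecord`), a set of such associations for a trait
(:class:`SumStats`), and an exposure/outcome pair aligned onto a shared
effect-allele frame (:class:`HarmonizedSet`).  Effect sizes are per copy of
the effect allele; for binary traits they live on the log-odds scale.

Harmonization follows the conservative two-sample MR conventions: outcome
effects are sign-flipped when the allele pair is swapped relative to the
exposure, strand-ambiguous (palindromic A/T, C/G) variants are dropped, and
allele pairs that match in neither orientation are dropped and counted rather
than strand-complemented.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: canonical column order of the summary-statistics TSV dialect
COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "n",
)

TRAIT_TYPES = ("quantitative", "binary")


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of one variant: rsID plus 1-based coordinate."""

    rsid: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class AssocRecord:
    """One variant's marginal association with one trait.

    ``beta`` is the per-effect-allele effect (log-odds for binary traits),
    ``se`` its standard error, ``pval`` the two-sided p-value.  ``eaf``
    (effect-allele frequency) and ``n`` (sample size) are optional.
    """

    key: VariantKey
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in NUCLEOTIDES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"pval must be in (0, 1], got {self.pval}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"eaf must be in (0, 1), got {self.eaf}")


@dataclass
class SumStats:
    """Summary statistics for one trait: a validated set of :class:`AssocRecord`."""

    trait_id: str
    trait_type: str
    records: list[AssocRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )
        rsids = [r.key.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"duplicate rsids in SumStats {self.trait_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.key.rsid for r in self.records]

    def record_map(self) -> dict[str, AssocRecord]:
        return {r.key.rsid: r for r in self.records}

    def subset(self, rsids: Sequence[str]) -> "SumStats":
        """New SumStats restricted to ``rsids``, in the order given."""
        rmap = self.record_map()
        missing = [r for r in rsids if r not in rmap]
        if missing:
            raise KeyError(f"rsids not present in {self.trait_id!r}: {missing[:5]}")
        return SumStats(self.trait_id, self.trait_type, [rmap[r] for r in rsids])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.key.rsid,
                r.key.chrom,
                r.key.pos,
                r.effect_allele,
                r.other_allele,
                r.beta,
                r.se,
                r.pval,
                r.eaf,
                r.n,
            )
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs expressed on a shared effect allele.

    ``table`` has columns rsid, beta_exp, se_exp, beta_out, se_out, flipped.
    ``flipped`` marks rows whose outcome alleles were swapped relative to the
    exposure (outcome beta already negated).
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0

    def __post_init__(self) -> None:
        if not (self.table["se_exp"] > 0).all() or not (self.table["se_out"] > 0).all():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return list(self.table["rsid"])

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(float)

    def drop(self, rsids: Iterable[str]) -> "HarmonizedSet":
        """New HarmonizedSet without the given rsids."""
        drop = set(rsids)
        keep = self.table[~self.table["rsid"].isin(drop)].reset_index(drop=True)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            keep,
            self.n_dropped_palindromic,
            self.n_dropped_unmatched,
        )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    pair = {effect_allele, other_allele}
    if not pair <= NUCLEOTIDES or len(pair) != 2:
        raise ValueError(f"invalid allele pair {effect_allele}/{other_allele}")
    return pair == {"A", "T"} or pair == {"C", "G"}


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    drop_palindromic: bool = True,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele frame.

    Inner join on rsid; swapped allele pairs get ``beta_out`` negated and are
    marked ``flipped``; pairs matching neither orientation are dropped and
    counted; palindromic variants are dropped when ``drop_palindromic``.

    Raises ``ValueError`` when no variants survive.
    """
    out_map = outcome.record_map()
    rows = []
    n_pal = 0
    n_unmatched = 0
    for rec in exposure.records:
        other = out_map.get(rec.key.rsid)
        if other is None:
            continue
        if drop_palindromic and is_palindromic(rec.effect_allele, rec.other_allele):
            n_pal += 1
            continue
        if (other.effect_allele, other.other_allele) == (
            rec.effect_allele,
            rec.other_allele,
        ):
            beta_out, flipped = other.beta, False
        elif (other.effect_allele, other.other_allele) == (
            rec.other_allele,
            rec.effect_allele,
        ):
            beta_out, flipped = -other.beta, True
        else:
            n_unmatched += 1
            continue
        rows.append((rec.key.rsid, rec.beta, rec.se, beta_out, other.se, flipped))
    if not rows:
        raise ValueError(
            f"no shared variants between {exposure.trait_id!r} and "
            f"{outcome.trait_id!r} after harmonization"
        )
    table = pd.DataFrame(
        rows, columns=["rsid", "beta_exp", "se_exp", "beta_out", "se_out", "flipped"]
    )
    return HarmonizedSet(
        exposure.trait_id, outcome.trait_id, table, n_pal, n_unmatched
    )


def _fmt_float(x: float | None, fmt: str) -> str:
    return "NA" if x is None else fmt % x


def write_sumstats(ss: SumStats, path: str | Path) -> None:
    """Write the fixed tab-separated dialect (header :data:`COLUMNS`).

    Betas, SEs and frequencies carry 10 significant digits; p-values use
    scientific notation.  ``read_sumstats`` inverts the format, and a second
    write of the re-read set is byte-identical.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in ss.records:
            fh.write(
                "\t".join(
                    (
                        r.key.rsid,
                        r.key.chrom,
                        str(r.key.pos),
                        r.effect_allele,
                        r.other_allele,
                        "%.10g" % r.beta,
                        "%.10g" % r.se,
                        "%.6e" % r.pval,
                        _fmt_float(r.eaf, "%.10g"),
                        "NA" if r.n is None else str(int(r.n)),
                    )
                )
                + "\n"
            )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
) -> SumStats:
    """Read a delimited summary-statistics table (tab or comma separated).

    ``column_map`` maps canonical names (:data:`COLUMNS`) to the file's
    column headers for heterogeneous inputs.  Rows violating the record
    invariants (non-positive SE, out-of-range p, bad alleles) are dropped
    with a logged count.  Raises on a missing file, a missing mapped column,
    or zero valid rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    colmap = dict(column_map or {})
    rename = {colmap.get(c, c): c for c in COLUMNS if colmap.get(c, c) in df.columns}
    df = df.rename(columns=rename)
    required = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            eaf = getattr(row, "eaf", None)
            n = getattr(row, "n", None)
            records.append(
                AssocRecord(
                    key=VariantKey(str(row.rsid), str(row.chrom), int(row.pos)),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                    n=None if n is None or pd.isna(n) else int(n),
                )
            )
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.warning("%s: dropped %d invalid rows", path, n_bad)
    if not records:
        raise ValueError(f"{path}: zero valid rows")
    return SumStats(
        trait_id=trait_id if trait_id is not None else path.stem,
        trait_type=trait_type,
        records=records,
    )
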
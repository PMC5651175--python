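"""Readers and writers for the tabular formats the toolkit consumes.

All genomic coordinates are held internally as 0-based, half-open
intervals.  SEG files are read and written in the common 1-based,
inclusive dialect by default; the conversion happens in exactly one
place (:func:`read_seg` / :func:`write_seg`).  Chromosome labels are
normalized by stripping any ``chr`` prefix, so mixed-source inputs
("chr17" vs "17") compare equal.

Formats handled here:

* SEG — tab-separated segmented copy-number (Sample, Chromosome,
  Start, End, Num_Probes, Segment_Mean);
* MAF-like TSV — somatic variant records with tumour/normal read
  counts and optional trinucleotide context / read-orientation counts;
* GMT — gene-set collections (name, description, genes...);
* matrix TSV — features x samples numeric matrices (first column is
  the feature id, header row carries sample ids);
* arm table — 5-column BED-like TSV (chrom, start, end, arm, callable);
* site lists — BED-like blacklists of genomic positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("esomix")

__all__ = [
    "GenomicSegment",
    "SegmentedCopyNumberProfile",
    "ArmDefinition",
    "OmicsMatrix",
    "GeneSetCollection",
    "VariantCall",
    "normalize_chromosome",
    "read_seg",
    "write_seg",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "write_maf",
    "read_matrix",
    "write_matrix",
    "read_arm_table",
    "write_arm_table",
    "read_site_list",
    "builtin_arm_table",
]

VALID_SCALES = {"RPKM", "RPM", "RSEM", "beta", "log2ratio", "zscore"}

ACROCENTRIC_P_ARMS = {"13p", "14p", "15p", "21p", "22p"}


class ParseError(ValueError):
    """A malformed line in an input file (carries the line number)."""


def normalize_chromosome(label: str) -> str:
    """Strip a ``chr`` prefix and canonicalize case of X/Y/MT labels."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"X", "Y", "MT", "M"}:
        return "MT" if s.upper() in {"MT", "M"} else s.upper()
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicSegment:
    """One segment of a copy-number profile (0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    n_probes: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if not self.start < self.end:
            raise ValueError(
                f"segment start must be < end, got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValueError("log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentedCopyNumberProfile:
    """Per-sample segmented log2 copy-ratio profile.

    Segments are sorted by (chromosome, start) on construction;
    overlapping segments within a chromosome are reported via the
    ``overlaps`` attribute (and logged) but not silently dropped.
    """

    sample_id: str
    segments: list[GenomicSegment]
    overlaps: list[tuple[GenomicSegment, GenomicSegment]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chromosome, s.start, s.end))
        self.overlaps = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chromosome == b.chromosome and b.start < a.end:
                self.overlaps.append((a, b))
        if self.overlaps:
            logger.warning(
                "sample %s: %d overlapping segment pair(s)",
                self.sample_id, len(self.overlaps),
            )


@dataclass(frozen=True)
class ArmDefinition:
    """A chromosome arm interval; ``callable=False`` marks arms (e.g.
    acrocentric p-arms) that are never scored."""

    arm_name: str
    chromosome: str
    start: int
    end: int
    callable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if not self.end > self.start:
            raise ValueError(f"arm {self.arm_name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


class OmicsMatrix:
    """Features x samples numeric matrix with a declared measurement scale.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = features,
    columns = samples) that enforces unique identifiers and, for beta
    values, the [0, 1] range.
    """

    def __init__(self, values: pd.DataFrame, scale: str):
        if scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {scale!r}; expected one of {sorted(VALID_SCALES)}")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if scale == "beta":
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")
        self.values = values.astype(float)
        self.scale = scale

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_rows(self, rows: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(rows)], self.scale)

    def subset_cols(self, cols: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(cols)], self.scale)

    def __repr__(self) -> str:
        r, c = self.shape
        return f"OmicsMatrix({r} features x {c} samples, scale={self.scale})"


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with one description per set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class VariantCall:
    """A somatic SNV record from one caller (position 0-based).

    ``context`` is the reference trinucleotide around the variant;
    ``alt_f1r2`` / ``alt_f2r1`` are read-orientation counts of the
    alternate allele, used by the oxoG artifact filter.
    """

    sample_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    t_ref_count: int
    t_alt_count: int
    n_ref_count: int
    n_alt_count: int
    caller: str
    context: str | None = None
    alt_f1r2: int | None = None
    alt_f2r1: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        for name in ("t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("alt_f1r2", "alt_f2r1"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.context is not None:
            if len(self.context) != 3:
                raise ValueError(f"context must have length 3, got {self.context!r}")
            if len(self.ref) == 1 and self.context[1].upper() != self.ref.upper():
                raise ValueError(
                    f"context middle base {self.context[1]!r} does not match "
                    f"ref allele {self.ref!r}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chromosome, self.position, self.ref, self.alt)

    @property
    def tumor_vaf(self) -> float:
        d = self.t_ref_count + self.t_alt_count
        return self.t_alt_count / d if d else float("nan")

    @property
    def normal_vaf(self) -> float:
        d = self.n_ref_count + self.n_alt_count
        return self.n_alt_count / d if d else float("nan")


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def _convert_in(start: int, end: int, convention: str) -> tuple[int, int]:
    if convention == "one_based_inclusive":
        return start - 1, end
    if convention == "zero_based_half_open":
        return start, end
    raise ValueError(f"unknown coordinate convention {convention!r}")


def _convert_out(start: int, end: int, convention: str) -> tuple[int, int]:
    if convention == "one_based_inclusive":
        return start + 1, end
    if convention == "zero_based_half_open":
        return start, end
    raise ValueError(f"unknown coordinate convention {convention!r}")


def read_seg(path: str | Path,
             convention: str = "one_based_inclusive",
             ) -> list[SegmentedCopyNumberProfile]:
    """Read a SEG file into per-sample profiles.

    Coordinates are converted to the internal 0-based half-open
    convention; segments come back sorted by (chromosome, start).
    """
    by_sample: dict[str, list[GenomicSegment]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file, expected a SEG header")
        cols = header.split("\t")
        idx = _seg_column_index(cols, path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                sample = fields[idx["sample"]]
                chrom = fields[idx["chromosome"]]
                start = int(fields[idx["start"]])
                end = int(fields[idx["end"]])
                mean = float(fields[idx["mean"]])
                nprobes = None
                if idx["nprobes"] is not None and fields[idx["nprobes"]] not in ("", "NA"):
                    nprobes = int(fields[idx["nprobes"]])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed SEG row: {exc}") from exc
            s0, e0 = _convert_in(start, end, convention)
            if s0 >= e0:
                raise ParseError(
                    f"{path}:{lineno}: start >= end after coordinate conversion "
                    f"({s0} >= {e0})"
                )
            seg = GenomicSegment(chrom, s0, e0, mean, nprobes)
            if sample not in by_sample:
                by_sample[sample] = []
                order.append(sample)
            by_sample[sample].append(seg)
    return [SegmentedCopyNumberProfile(s, by_sample[s]) for s in order]


def _seg_column_index(cols: list[str], path) -> dict:
    low = [c.strip().lower() for c in cols]

    def find(*names, required=True):
        for n in names:
            if n in low:
                return low.index(n)
        if required:
            raise ParseError(f"{path}: SEG header lacks a column among {names}")
        return None

    return {
        "sample": find("sample", "id", "sample_id"),
        "chromosome": find("chromosome", "chrom", "chr"),
        "start": find("start", "loc.start", "start_position"),
        "end": find("end", "loc.end", "end_position"),
        "mean": find("segment_mean", "seg.mean", "mean", "log2"),
        "nprobes": find("num_probes", "num.mark", "nprobes", required=False),
    }


def write_seg(profiles: Iterable[SegmentedCopyNumberProfile],
              path: str | Path,
              convention: str = "one_based_inclusive") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for prof in profiles:
            for seg in prof.segments:
                s, e = _convert_out(seg.start, seg.end, convention)
                np_field = "" if seg.n_probes is None else str(seg.n_probes)
                fh.write(
                    f"{prof.sample_id}\t{seg.chromosome}\t{s}\t{e}\t"
                    f"{np_field}\t{seg.log2_ratio:.6g}\n"
                )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...), deduplicating genes
    within a line with a warning."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains %d duplicated gene(s); deduplicated",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# MAF-like TSV
# ---------------------------------------------------------------------------

MAF_REQUIRED = [
    "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2",
    "t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count", "caller",
]
MAF_OPTIONAL = ["context", "alt_f1r2", "alt_f2r1"]


def read_maf(path: str | Path) -> list[VariantCall]:
    """Read a MAF-like TSV into :class:`VariantCall` records.

    Positions in the file are 1-based (MAF convention) and converted
    to 0-based internally.  Missing optional columns yield ``None``
    fields, never zeros.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MAF lacks required columns {missing}")
    calls: list[VariantCall] = []
    has = {c: c in df.columns for c in MAF_OPTIONAL}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            counts = {c: int(rec[c]) for c in
                      ("t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count")}
            for c, v in counts.items():
                if v < 0:
                    raise ValueError(f"negative read count in column {c}")
            kwargs = dict(
                sample_id=rec["Tumor_Sample_Barcode"],
                chromosome=rec["Chromosome"],
                position=int(rec["Start_Position"]) - 1,
                ref=rec["Reference_Allele"],
                alt=rec["Tumor_Seq_Allele2"],
                caller=rec["caller"],
                **counts,
            )
            for c in MAF_OPTIONAL:
                if has[c] and not _is_na(rec[c]):
                    kwargs[c] = rec[c] if c == "context" else int(rec[c])
            calls.append(VariantCall(**kwargs))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: bad MAF record: {exc}") from exc
    return calls


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "NA", ".")


def write_maf(calls: Iterable[VariantCall], path: str | Path,
              extra_columns: dict[str, list] | None = None,
              header_comment: str | None = None) -> None:
    """Write VariantCall records as MAF-like TSV (1-based positions)."""
    calls = list(calls)
    cols = MAF_REQUIRED + MAF_OPTIONAL
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"#{line}\n")
        extra = extra_columns or {}
        fh.write("\t".join(cols + list(extra)) + "\n")
        for i, v in enumerate(calls):
            row = [
                v.sample_id, v.chromosome, str(v.position + 1), v.ref, v.alt,
                str(v.t_ref_count), str(v.t_alt_count),
                str(v.n_ref_count), str(v.n_alt_count), v.caller,
                v.context if v.context is not None else "",
                "" if v.alt_f1r2 is None else str(v.alt_f1r2),
                "" if v.alt_f2r1 is None else str(v.alt_f2r1),
            ]
            row += [str(extra[c][i]) for c in extra]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str) -> OmicsMatrix:
    """Read a features-x-samples TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df, scale)


def write_matrix(m: OmicsMatrix, path: str | Path,
                 header_comment: str | None = None,
                 float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"#{line}\n")
        m.values.to_csv(fh, sep="\t", index_label="feature",
                        float_format=float_format)


# ---------------------------------------------------------------------------
# arm tables and site lists
# ---------------------------------------------------------------------------

def read_arm_table(path: str | Path) -> list[ArmDefinition]:
    """Read a BED-like arm table: chrom, start, end, arm_name, callable."""
    arms: list[ArmDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: arm table needs 5 columns")
            chrom, start, end, name, call = fields[:5]
            arms.append(ArmDefinition(
                arm_name=name, chromosome=chrom,
                start=int(start), end=int(end),
                callable=call.strip().lower() in ("1", "true", "yes"),
            ))
    _check_arm_overlaps(arms)
    return arms


def _check_arm_overlaps(arms: Sequence[ArmDefinition]) -> None:
    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda a: a.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"arms {a.arm_name} and {b.arm_name} overlap on chromosome {chrom}"
                )


def write_arm_table(arms: Iterable[ArmDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tarm\tcallable\n")
        for a in arms:
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\t{a.arm_name}\t"
                     f"{'1' if a.callable else '0'}\n")


# Approximate GRCh37 centromere-split arm boundaries (Mb resolution).
# Sufficient for arm-level fraction arithmetic; acrocentric p-arms are
# marked non-callable by default.
_ARM_BOUNDS_MB = {
    "1": (125, 249), "2": (93, 243), "3": (91, 198), "4": (50, 191),
    "5": (48, 181), "6": (61, 171), "7": (60, 159), "8": (45, 146),
    "9": (49, 141), "10": (40, 136), "11": (53, 135), "12": (36, 134),
    "13": (18, 115), "14": (17, 107), "15": (19, 103), "16": (37, 90),
    "17": (24, 81), "18": (17, 78), "19": (26, 59), "20": (28, 63),
    "21": (13, 48), "22": (15, 51),
}


def builtin_arm_table() -> list[ArmDefinition]:
    """Autosomal arm definitions at megabase resolution (GRCh37-like)."""
    mb = 1_000_000
    arms = []
    for chrom, (cen, length) in _ARM_BOUNDS_MB.items():
        p_callable = f"{chrom}p" not in ACROCENTRIC_P_ARMS
        arms.append(ArmDefinition(f"{chrom}p", chrom, 0, cen * mb, p_callable))
        arms.append(ArmDefinition(f"{chrom}q", chrom, cen * mb, length * mb, True))
    return arms


def read_site_list(path: str | Path) -> set[tuple[str, int, str]]:
    """Read a BED-like blacklist into (chromosome, position, alt) keys.

    Columns: chrom, start, end (0-based half-open); optional 4th column
    gives the alternate allele, ``*`` (or absence) matches any alt.
    """
    sites: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED-like line needs >= 3 columns")
            chrom = normalize_chromosome(fields[0])
            start, end = int(fields[1]), int(fields[2])
            alt = fields[3] if len(fields) > 3 and fields[3] else "*"
            for pos in range(start, end):
                sites.add((chrom, pos, alt))
    return sites
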
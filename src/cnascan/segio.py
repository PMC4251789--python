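"""Domain types and I/O for allele-specific copy-number segment data.

The central object is a :class:`SampleProfile`: one tumour genome described as
an ordered list of autosomal segments, each carrying absolute allele-specific
copy numbers ``(total_cn, minor_cn)`` as produced by purity/ploidy-aware
callers (TAPS, ASCAT, ABSOLUTE and relatives).  A state is conventionally
written ``"2m1"`` (two copies total, one copy of the minor allele) — the
normal heterozygous diploid state — while e.g. ``"2m0"`` is copy-neutral loss
of heterozygosity and ``"4m2"`` the balanced post-duplication state.

Coordinates are 0-based half-open internally.  Segment files on disk follow
the SEG convention (1-based inclusive) unless told otherwise; arm-definition
files are BED-style (0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

AUTOSOMES = tuple(range(1, 23))

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


class SegmentFileError(ValueError):
    """Malformed segment/metadata/arm file content."""


class ValidationError(ValueError):
    """Structurally parseable but semantically invalid input."""


def _parse_chrom(value) -> int:
    """Normalise a chromosome label to an autosome integer 1..22."""
    text = str(value).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    if text in ("X", "x", "Y", "y", "23", "24"):
        raise ValidationError(f"sex chromosome {value!r} not supported; autosomes only")
    try:
        chrom = int(text)
    except ValueError as exc:
        raise SegmentFileError(f"unrecognised chromosome label {value!r}") from exc
    if chrom not in AUTOSOMES:
        raise ValidationError(f"chromosome {chrom} outside autosome range 1..22")
    return chrom


@dataclass(frozen=True, slots=True)
class GenomeSegment:
    """A genomic interval with absolute allele-specific copy number.

    ``minor_cn`` is the copy number of the less-abundant parental allele, so
    ``minor_cn <= total_cn - minor_cn`` always holds; use
    :func:`canonical_state` to fold raw (total, minor) pairs into this form.
    """

    chrom: int
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.chrom not in AUTOSOMES:
            raise ValidationError(f"chromosome {self.chrom} is not an autosome")
        if not self.start < self.end:
            raise ValidationError(
                f"empty or inverted interval [{self.start}, {self.end}) on chr{self.chrom}"
            )
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValidationError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValidationError(
                f"minor_cn {self.minor_cn} exceeds the major allele for total_cn "
                f"{self.total_cn}; canonicalise first"
            )
        if self.total_cn == 0 and self.minor_cn != 0:
            raise ValidationError("total_cn 0 requires minor_cn 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    def __str__(self) -> str:  # "4m2"-style state label
        return f"chr{self.chrom}:{self.start}-{self.end} {self.total_cn}m{self.minor_cn}"


def canonical_state(total_cn: int, minor_cn: int) -> tuple[int, int]:
    """Fold (total, minor) so that minor is the lesser homolog.

    Callers sometimes emit the two allele copy numbers in arbitrary order;
    a row like total=1, minor=1 really means one copy of one allele and zero
    of the other, i.e. (1, 0).
    """
    return total_cn, min(minor_cn, total_cn - minor_cn)


@dataclass(frozen=True, slots=True)
class ArmDefinition:
    """One chromosome arm (p or q) as a half-open interval."""

    chrom: int
    arm: Literal["p", "q"]
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass(frozen=True)
class SampleProfile:
    """One tumour genome as sorted, non-overlapping autosomal segments.

    Gaps between segments are permitted and treated as missing data
    (uncallable regions) by all downstream computations.
    """

    sample_id: str
    segments: tuple[GenomeSegment, ...]

    def __init__(self, sample_id: str, segments: Iterable[GenomeSegment]):
        segs = tuple(sorted(segments, key=lambda s: (s.chrom, s.start)))
        for prev, cur in zip(segs, segs[1:]):
            if prev.chrom == cur.chrom and cur.start < prev.end:
                raise ValidationError(
                    f"sample {sample_id}: overlapping segments on chr{cur.chrom} "
                    f"([{prev.start},{prev.end}) and [{cur.start},{cur.end}))"
                )
        object.__setattr__(self, "sample_id", sample_id)
        object.__setattr__(self, "segments", segs)

    def chromosomes(self) -> list[int]:
        return sorted({s.chrom for s in self.segments})

    def segments_on(self, chrom: int) -> list[GenomeSegment]:
        return [s for s in self.segments if s.chrom == chrom]

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)


Stage = Literal["II", "III", "IV"]


@dataclass(frozen=True, slots=True)
class SampleMetadata:
    """Clinical annotation for one sample.

    MSI-Low behaves like microsatellite-stable disease and is merged into
    MSS at parse time, so ``msi`` is binary.
    """

    sample_id: str
    stage: Stage
    msi: Literal["MSI-H", "MSS"]
    distant_recurrence: bool
    followup_years: float | None
    adjuvant_chemo: bool = False


def label_dissemination(meta: SampleMetadata) -> bool:
    """True if the tumour disseminated: stage IV at diagnosis, or distant
    recurrence within 5 years for stage II-III disease."""
    if meta.stage == "IV":
        return True
    if meta.distant_recurrence:
        if meta.followup_years is None:
            return True
        return meta.followup_years <= 5.0
    return False


def is_analysable(meta: SampleMetadata) -> bool:
    """Stage II-III samples without recurrence need >5 years of follow-up for
    a negative dissemination label to be trustworthy."""
    if meta.stage in ("II", "III") and not meta.distant_recurrence:
        return meta.followup_years is not None and meta.followup_years > 5.0
    return True


def filter_analysable(metas: Sequence[SampleMetadata]) -> list[SampleMetadata]:
    """Drop non-analysable samples, warning about each exclusion."""
    kept = []
    for m in metas:
        if is_analysable(m):
            kept.append(m)
        else:
            warnings.warn(
                f"excluding {m.sample_id}: stage {m.stage} without recurrence and "
                f"follow-up {m.followup_years} y (need > 5 y)",
                stacklevel=2,
            )
    return kept


# ---------------------------------------------------------------------------
# segment file I/O


def parse_segment_file(path, dialect: Literal["seg", "bed"] = "seg") -> list[SampleProfile]:
    """Read a tab-separated allele-specific segment table into profiles.

    Expected header columns: sample, chrom, start, end, total_cn, minor_cn.
    ``dialect="seg"`` (default) treats file coordinates as 1-based inclusive;
    ``dialect="bed"`` as 0-based half-open.  Copy-number pairs are
    canonicalised so that minor is the lesser allele.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise SegmentFileError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentFileError(f"{path}: missing columns {missing}")

    offset = 1 if dialect == "seg" else 0
    by_sample: dict[str, list[GenomeSegment]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            total = int(row.total_cn)
            minor = int(row.minor_cn)
            start = int(row.start)
            end = int(row.end)
        except ValueError as exc:
            raise SegmentFileError(
                f"{path} line {i}: non-integer field ({exc})"
            ) from exc
        chrom = _parse_chrom(row.chrom)
        total, minor = canonical_state(total, minor)
        seg = GenomeSegment(chrom, start - offset, end, total, minor)
        by_sample.setdefault(str(row.sample), []).append(seg)
    return [SampleProfile(sid, segs) for sid, segs in by_sample.items()]


def write_segment_file(profiles: Sequence[SampleProfile], path,
                       dialect: Literal["seg", "bed"] = "seg") -> None:
    """Serialise profiles in the same tabular dialects parse_segment_file reads."""
    offset = 1 if dialect == "seg" else 0
    rows = [
        (p.sample_id, s.chrom, s.start + offset, s.end, s.total_cn, s.minor_cn)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


_META_COLUMNS = ["sample", "stage", "msi", "distant_recurrence", "followup_years",
                 "adjuvant_chemo"]

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_flag(value, where: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text == "nan":
        return False
    raise SegmentFileError(f"{where}: cannot interpret flag {value!r}")


def parse_metadata(path) -> list[SampleMetadata]:
    """Read the clinical metadata table (tab-separated with header).

    MSI values MSI-L/MSI-Low are merged into MSS; stage accepts II/III/IV or
    2/3/4.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentFileError(f"{path}: missing columns {missing}")
    stage_map = {"2": "II", "3": "III", "4": "IV", "II": "II", "III": "III", "IV": "IV"}
    metas = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        stage = stage_map.get(str(row.stage).strip())
        if stage is None:
            raise SegmentFileError(f"{path} line {i}: bad stage {row.stage!r}")
        msi_raw = str(row.msi).strip().upper().replace("_", "-")
        if msi_raw in ("MSI-H", "MSI-HIGH", "MSI"):
            msi = "MSI-H"
        elif msi_raw in ("MSS", "MSI-L", "MSI-LOW"):
            msi = "MSS"
        else:
            raise SegmentFileError(f"{path} line {i}: bad MSI status {row.msi!r}")
        fy = str(row.followup_years).strip()
        followup = None if fy in ("", ".", "nan", "NA") else float(fy)
        metas.append(
            SampleMetadata(
                sample_id=str(row.sample),
                stage=stage,
                msi=msi,
                distant_recurrence=_parse_flag(row.distant_recurrence, f"{path} line {i}"),
                followup_years=followup,
                adjuvant_chemo=_parse_flag(row.adjuvant_chemo, f"{path} line {i}"),
            )
        )
    return metas


def write_metadata(metas: Sequence[SampleMetadata], path) -> None:
    rows = [
        (m.sample_id, m.stage, m.msi, int(m.distant_recurrence),
         "" if m.followup_years is None else m.followup_years, int(m.adjuvant_chemo))
        for m in metas
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# arm definitions


def parse_arm_file(path) -> list[ArmDefinition]:
    """Read arm definitions: BED-style TSV with columns chrom, start, end, arm."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["chrom", "start", "end", "arm"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SegmentFileError(f"{path}: missing columns {missing}")
    arms = []
    for row in df.itertuples(index=False):
        arm = str(row.arm).strip()
        if arm not in ("p", "q"):
            raise SegmentFileError(f"{path}: arm must be p or q, got {row.arm!r}")
        arms.append(ArmDefinition(_parse_chrom(row.chrom), arm, int(row.start), int(row.end)))
    arms.sort(key=lambda a: (a.chrom, a.start))
    for p, q in zip(arms, arms[1:]):
        if p.chrom == q.chrom and p.end > q.start:
            raise ValidationError(f"arms overlap on chr{p.chrom}")
    return arms


def default_arms() -> list[ArmDefinition]:
    """The bundled hg19 autosome arm table (44 arms; p ends at the centromere
    gap start, q begins at its end)."""
    with resources.files("cnascan.data").joinpath("hg19_arms.tsv").open() as fh:
        return parse_arm_file(fh)


# ---------------------------------------------------------------------------
# track output


def write_bedgraph(intervals: Sequence[tuple[int, int, int]],
                   values: Sequence[float], path) -> None:
    """Write (chrom, start, end) intervals with one value each as bedGraph.

    Input must be position-sorted; 0-based half-open coordinates as bedGraph
    requires.
    """
    prev = None
    lines = []
    for (chrom, start, end), val in zip(intervals, values, strict=True):
        key = (chrom, start)
        if prev is not None and key < prev:
            raise ValidationError("bedGraph intervals must be position-sorted")
        prev = key
        lines.append(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")
    Path(path).write_text("".join(lines))
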
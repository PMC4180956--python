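"""Cell-prevalence (CP) estimation from somatic event measurements.

Cell prevalence is the fraction of cells in a bulk sample that carry a
given somatic event.  Every downstream step (clustering, subclone tree
enumeration, co-localization) operates purely on CP values, which makes
the framework agnostic to the underlying variant type: copy-number
changes, loss of heterozygosity and point mutations are all reduced to
CP here.

Conversions implemented:

* CNV: a segment's relative copy number ``RCN = 2 * 2**log2_ratio`` and
  its called absolute copy number ``ACN`` give
  ``CP = (RCN - 2) / (ACN - 2)`` (a two-population mixture of normal
  diploid cells and event-bearing cells).
* LOH: with segmental mirrored-BAF mean ``u`` and absolute copy number
  ``n``, ``CP = (2u - 1) / (n (1 - u) + (2u - 1))``.
* SNV: in diploid context, ``CP = 2 * AF`` for heterozygous calls and
  ``CP = AF`` for homozygous calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SegmentMeasurement",
    "SNVMeasurement",
    "CPEvent",
    "ParameterError",
    "CopyNeutralError",
    "InconsistentACNError",
    "AbnormalAlleleFrequencyError",
    "UnsupportedContextError",
    "rcn_from_log2ratio",
    "call_acn",
    "cp_from_cnv",
    "mbaf_from_baf",
    "cp_from_loh",
    "cp_from_snv",
    "events_from_segments",
    "events_from_snvs",
]

#: tolerance within which out-of-range CP values are clamped rather than rejected
CP_TOL = 1e-6


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class CopyNeutralError(ValueError):
    """A copy-neutral segment (RCN == 2) carries no CNV event."""


class InconsistentACNError(ValueError):
    """The RCN/ACN combination implies a cell prevalence outside [0, 1]."""


class AbnormalAlleleFrequencyError(ValueError):
    """Heterozygous diploid AF above 50 percent: the event is flagged and excluded."""


class UnsupportedContextError(NotImplementedError):
    """SNV CP in non-diploid context requires external estimation (e.g. PyClone)."""


@dataclass(frozen=True)
class SegmentMeasurement:
    """One copy-number / LOH segment.

    Coordinates are 0-based half-open (BED convention).  ``mbaf_mean`` is
    the segmental mirrored-BAF mean ``u`` in [0.5, 1], when available.
    """

    chrom: str
    start: int
    end: int
    log2_ratio: float
    sample_id: str
    mbaf_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ParameterError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.mbaf_mean is not None and not (0.5 <= self.mbaf_mean <= 1.0):
            raise ParameterError(f"mbaf_mean {self.mbaf_mean} outside [0.5, 1]")


@dataclass(frozen=True)
class SNVMeasurement:
    """One somatic SNV with its bulk allele frequency (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    sample_id: str
    zygosity: str = "heterozygous"

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ParameterError(f"allele frequency {self.af} outside [0, 1]")
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise ParameterError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class CPEvent:
    """A somatic event reduced to a per-sample cell prevalence."""

    event_id: str
    sample_id: str
    cp: float
    source: str  # "cnv" | "loh" | "snv"
    measurement: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.cp <= 1.0):
            raise ParameterError(f"cell prevalence {self.cp} outside [0, 1]")
        if self.source not in ("cnv", "loh", "snv"):
            raise ParameterError(f"unknown event source {self.source!r}")


def rcn_from_log2ratio(log2_ratio: float, purity: float = 1.0) -> float:
    """Relative copy number from a segmental log2(tumor/normal) ratio.

    On the raw scale ``RCN = 2 * 2**log2_ratio``.  With tumor purity
    ``q < 1`` the observed signal is a mixture with ``2(1-q)`` copies of
    normal DNA, inverted as ``(RCN_raw - 2(1-q)) / q`` and clamped below
    at zero.
    """
    if not (0.0 < purity <= 1.0):
        raise ParameterError(f"purity {purity} outside (0, 1]")
    raw = 2.0 * 2.0 ** log2_ratio
    if purity == 1.0:
        return raw
    return max(0.0, (raw - 2.0 * (1.0 - purity)) / purity)


def call_acn(rcn: float, loh_flag: bool = False) -> int:
    """Call the integer absolute copy number of a CNV segment.

    Deletions: RCN in (1, 2) is a heterozygous deletion (ACN 1) unless
    high LOH is observed (``loh_flag``), in which case a homozygous
    deletion (ACN 0) is called; RCN <= 1 is always a homozygous deletion.
    Amplifications take the smallest integer ACN >= 3 whose implied CP
    ``(RCN-2)/(ACN-2)`` lies in [0, 1] — the most parsimonious gain.
    """
    if rcn < 0:
        raise ParameterError(f"negative RCN {rcn}")
    if rcn == 2:
        raise CopyNeutralError("copy-neutral segment has no CNV event")
    if rcn < 2:
        if rcn <= 1:
            return 0
        return 0 if loh_flag else 1
    return max(3, math.ceil(rcn))


def cp_from_cnv(rcn: float, acn: int) -> float:
    """Cell prevalence of a CNV event: ``(RCN - 2) / (ACN - 2)``."""
    if acn == 2:
        raise ParameterError("ACN 2 is copy-neutral; CP is undefined (division by zero)")
    cp = (rcn - 2.0) / (acn - 2.0)
    if cp < -CP_TOL or cp > 1.0 + CP_TOL:
        raise InconsistentACNError(
            f"RCN {rcn} with ACN {acn} implies CP {cp:.6g} outside [0, 1]"
        )
    return min(1.0, max(0.0, cp))


def mbaf_from_baf(baf: float) -> float:
    """Mirror a B-allele frequency onto [0.5, 1]: ``BAF if BAF >= 0.5 else 1 - BAF``."""
    if not (0.0 <= baf <= 1.0):
        raise ParameterError(f"BAF {baf} outside [0, 1]")
    return baf if baf >= 0.5 else 1.0 - baf


def cp_from_loh(u: float, acn: int) -> float:
    """Cell prevalence of an LOH event from segmental mBAF mean ``u``.

    ``CP = (2u - 1) / (n (1 - u) + (2u - 1))`` with ``n`` the segment ACN.
    """
    if not (0.5 <= u <= 1.0):
        raise ParameterError(f"mBAF mean {u} outside [0.5, 1]")
    if acn < 1:
        raise ParameterError(f"ACN {acn} must be >= 1 for an LOH segment")
    denom = acn * (1.0 - u) + (2.0 * u - 1.0)
    if denom <= 0:
        raise ParameterError(f"degenerate denominator {denom} for u={u}, n={acn}")
    return (2.0 * u - 1.0) / denom


def cp_from_snv(af: float, zygosity: str, local_acn: Optional[int] = None) -> float:
    """Cell prevalence of an SNV in a copy-number-neutral (diploid) region.

    Heterozygous: ``CP = 2 * AF`` (an AF of 30% means 60% of cells carry
    the variant on one of two copies).  Homozygous: ``CP = AF``.
    Heterozygous AF above 0.5 cannot arise in a diploid region and is
    rejected; SNVs inside CNV regions need allele-specific CP estimation
    upstream and are not handled here.
    """
    if not (0.0 <= af <= 1.0):
        raise ParameterError(f"allele frequency {af} outside [0, 1]")
    if local_acn is not None and local_acn != 2:
        raise UnsupportedContextError(
            "SNV CP in non-diploid regions requires external estimation "
            "(e.g. PyClone); supply the CP directly via the cluster table input"
        )
    if zygosity == "homozygous":
        return af
    if zygosity != "heterozygous":
        raise ParameterError(f"unknown zygosity {zygosity!r}")
    cp = 2.0 * af
    if cp > 1.0 + CP_TOL:
        raise AbnormalAlleleFrequencyError(
            f"heterozygous AF {af} > 0.5 in diploid context: abnormal event, excluded"
        )
    if cp > 1.0:
        warnings.warn(f"heterozygous AF {af} marginally above 0.5; CP capped at 1")
        cp = 1.0
    return cp


def events_from_segments(
    segments,
    purity: float = 1.0,
    copy_neutral_log2_tol: float = 0.1,
    loh_mbaf_threshold: float = 0.9,
):
    """Convert segment measurements into CP events.

    Segments within ``copy_neutral_log2_tol`` of log2 ratio 0 are treated
    as copy-neutral: they yield an LOH event when the mirrored-BAF mean
    shows allelic imbalance (u > 0.5), otherwise no event.  Other
    segments go through the RCN -> ACN -> CP route; an mBAF mean at or
    above ``loh_mbaf_threshold`` flags "significant high LOH", turning a
    heterozygous-deletion call into a homozygous one.
    """
    events = []
    for seg in segments:
        eid = f"{seg.chrom}:{seg.start}-{seg.end}"
        if abs(seg.log2_ratio) <= copy_neutral_log2_tol:
            if seg.mbaf_mean is not None and seg.mbaf_mean > 0.5:
                cp = cp_from_loh(seg.mbaf_mean, 2)
                events.append(CPEvent(eid, seg.sample_id, cp, "loh", seg))
            continue
        rcn = rcn_from_log2ratio(seg.log2_ratio, purity)
        loh_flag = seg.mbaf_mean is not None and seg.mbaf_mean >= loh_mbaf_threshold
        try:
            acn = call_acn(rcn, loh_flag)
            cp = cp_from_cnv(rcn, acn)
        except (CopyNeutralError, InconsistentACNError) as exc:
            warnings.warn(f"segment {eid} skipped: {exc}")
            continue
        events.append(CPEvent(eid, seg.sample_id, cp, "cnv", seg))
    return events


def events_from_snvs(snvs):
    """Convert SNV measurements into CP events, excluding abnormal AFs."""
    events = []
    for snv in snvs:
        eid = f"{snv.chrom}:{snv.pos}:{snv.ref}>{snv.alt}"
        try:
            cp = cp_from_snv(snv.af, snv.zygosity)
        except AbnormalAlleleFrequencyError as exc:
            warnings.warn(str(exc))
            continue
        events.append(CPEvent(eid, snv.sample_id, cp, "snv", snv))
    return events
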
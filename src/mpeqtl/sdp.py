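"""SNP distribution patterns (SDPs) for a four-founder cross.

An SDP is the partition of the four founder strains into carriers and
non-carriers of a SNP allele.  Because a subset and its complement induce
the same partition, the 14 proper, non-empty subsets of the four founders
collapse into 7 informative classes.  The canonical representative of each
class is the subset containing the first founder (JU1511); singleton
classes are displayed by the strain name, founder pairs containing JU1511
by the two-digit code of the pair ("12", "13", "14").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable

FOUNDERS: tuple[str, str, str, str] = ("JU1511", "JU1926", "JU1931", "JU1941")

_FOUNDER_DIGIT = {name: str(i + 1) for i, name in enumerate(FOUNDERS)}

#: The 7 display labels, in the fixed order used throughout reports.
SDP_LABELS: tuple[str, ...] = ("12", "13", "14", "JU1511", "JU1926", "JU1931", "JU1941")


@dataclass(frozen=True)
class SdpLabel:
    """Canonical SNP-distribution-pattern label.

    Parameters
    ----------
    carriers
        Canonical carrier subset (the representative containing JU1511,
        or the singleton for singleton/triple classes).
    display
        One of the 7 display labels.
    """

    carriers: FrozenSet[str]
    display: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.display


def canonical_sdp(carriers: Iterable[str]) -> SdpLabel:
    """Canonicalize a carrier subset into one of the 7 SDP classes.

    A subset and its complement map to the same label.  Raises
    ``ValueError`` for the empty or full set (non-informative) or for
    unknown strain names.
    """
    subset = frozenset(carriers)
    unknown = subset - set(FOUNDERS)
    if unknown:
        raise ValueError(f"unknown founder strain(s): {sorted(unknown)}")
    if not subset or subset == frozenset(FOUNDERS):
        raise ValueError("SDP carrier set must be a proper, non-empty subset of the founders")
    complement = frozenset(FOUNDERS) - subset
    # Singleton classes (subset or complement of size 1) display the strain name.
    if len(subset) == 1:
        return SdpLabel(subset, next(iter(subset)))
    if len(complement) == 1:
        return SdpLabel(complement, next(iter(complement)))
    # Pair classes: canonical representative contains JU1511.
    canon = subset if FOUNDERS[0] in subset else complement
    other = next(iter(canon - {FOUNDERS[0]}))
    return SdpLabel(canon, "1" + _FOUNDER_DIGIT[other])


def sdp_from_display(display: str) -> SdpLabel:
    """Recover the canonical label from its display string."""
    if display in FOUNDERS:
        return SdpLabel(frozenset({display}), display)
    if display in {"12", "13", "14"}:
        other = FOUNDERS[int(display[1]) - 1]
        return SdpLabel(frozenset({FOUNDERS[0], other}), display)
    raise ValueError(f"not an SDP display label: {display!r}")
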
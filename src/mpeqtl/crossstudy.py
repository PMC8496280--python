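"""Cross-study comparison of genes with eQTLs.

External eQTL experiments are summarized as per-gene peak calls from
their significance profiles (most significant marker per gene, called
at -log10(p) > 3.5 by default, cis/trans by the 1-Mbp start-distance
rule with that study's own marker map and annotation).  Overlap between
two studies is on gene identity per eQTL type, expressed as a
percentage of the reference study's calls — so the comparison is
deliberately asymmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneAnnotation, GenotypeMatrix
from .eqtl import call_peaks_frame, classify_records_frame


@dataclass
class StudyEqtlCalls:
    """Per-gene eQTL calls of one study: one row per called gene."""

    study: str
    calls: pd.DataFrame  # index gene; columns chromosome, position, neglogp, type

    def genes_of_type(self, type: str) -> set[str]:
        if type not in ("cis", "trans"):
            raise ValueError("type must be 'cis' or 'trans'")
        return set(self.calls.index[self.calls["type"] == type])


def call_external(
    study: str,
    profiles: pd.DataFrame,
    genos: GenotypeMatrix,
    ann: dict[str, GeneAnnotation],
    threshold: float = 3.5,
    window: int = 1_000_000,
) -> StudyEqtlCalls:
    """Call eQTLs from an external genes x markers -log10(p) profile table.

    Only genes whose peak strictly exceeds ``threshold`` are called.
    Marker columns must match the study's marker map; genes must be
    annotated.
    """
    missing_m = [c for c in profiles.columns if c not in set(genos.alleles.index)]
    if missing_m:
        raise ValueError(f"profile marker(s) absent from the marker map: {missing_m[:5]}")
    profiles = profiles.loc[:, [m.id for m in genos.markers]]
    slopes = pd.DataFrame(np.nan, index=profiles.index, columns=profiles.columns)
    peaks = call_peaks_frame(profiles, slopes, genos, threshold)
    called = peaks[peaks["significant"]]
    called = classify_records_frame(called, ann, window)
    return StudyEqtlCalls(
        study, called[["chromosome", "position", "neglogp", "type"]].copy()
    )


def overlap_percentage(
    ours: StudyEqtlCalls, theirs: StudyEqtlCalls, type: str
) -> float:
    """100 x |shared genes of this type| / |genes of this type in ``theirs``|.

    NaN with a warning when the reference study has no calls of the type.
    """
    a = ours.genes_of_type(type)
    b = theirs.genes_of_type(type)
    if not b:
        warnings.warn(f"study {theirs.study} has no {type} calls; overlap undefined")
        return float("nan")
    return 100.0 * len(a & b) / len(b)


def compare_studies(
    ours: StudyEqtlCalls, others: list[StudyEqtlCalls]
) -> pd.DataFrame:
    """Report-style overlap table: per study, call totals and overlap %."""
    rows = []
    for st in others:
        cis, trans = st.genes_of_type("cis"), st.genes_of_type("trans")
        rows.append(
            {
                "study": st.study,
                "total_cis": len(cis),
                "cis_overlap_pct": overlap_percentage(ours, st, "cis") if cis else float("nan"),
                "total_trans": len(trans),
                "trans_overlap_pct": overlap_percentage(ours, st, "trans") if trans else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("study")
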
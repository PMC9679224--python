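"""Composition-based protein flexibility scoring.

Residues are partitioned by a flexibility index into very flexible
(Vf: E, G, K, N, Q, S), moderately flexible (Mf: A, D, H, I, P, R, T, V)
and the rigid complement (C, F, L, M, W, Y).  Per-protein percentages of
those classes are the pipeline's primary flexibility metrics; externally
predicted per-protein flexibility classes M0/M1/M2 (rigid to flexible) can
be attached from a table and are propagated through the same aggregation
machinery (M1+2 = M1 + M2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .sequence_io import CdsRecord

logger = logging.getLogger(__name__)

VF_RESIDUES = frozenset("EGKNQS")
MF_RESIDUES = frozenset("ADHIPRTV")
RIGID_RESIDUES = frozenset("CFLMWY")
STANDARD_AA = VF_RESIDUES | MF_RESIDUES | RIGID_RESIDUES

GLOBAL_PATHWAY = "global"
COMPOSITION_METRICS = ("Vf", "VMf")
EXTERNAL_METRICS = ("M2", "M1+2")


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-protein flexibility percentages.

    ``vf + mf + rigid == 100`` up to floating tolerance and ``vmf = vf + mf``.
    The M fields are ``None`` until an external prediction table is attached.
    """

    protein_id: str
    vf_percent: float
    mf_percent: float
    vmf_percent: float
    rigid_percent: float
    m0_percent: float | None = None
    m1_percent: float | None = None
    m2_percent: float | None = None
    m12_percent: float | None = None


_warned_x = 0


def residue_class(aa: str) -> str:
    """Flexibility class of a one-letter residue code: Vf, Mf or rigid.

    ``X`` is counted as rigid with a warning; anything else is rejected.
    """
    global _warned_x
    if aa in VF_RESIDUES:
        return "Vf"
    if aa in MF_RESIDUES:
        return "Mf"
    if aa in RIGID_RESIDUES:
        return "rigid"
    if aa == "X":
        _warned_x += 1
        logger.warning("residue X has no flexibility class; treated as rigid")
        return "rigid"
    raise ValueError(f"unknown residue symbol {aa!r}")


def flexibility_profile(protein_id: str, peptide: str) -> FlexibilityProfile:
    """Percentages of Vf/Mf/rigid residues in a peptide.

    ``X`` residues are excluded from numerator and denominator; terminal
    stops must already be stripped.  This is a pure composition statistic,
    invariant under any permutation of the peptide.
    """
    peptide = peptide.rstrip("*")
    counted = [aa for aa in peptide if aa != "X"]
    for aa in counted:
        if aa not in STANDARD_AA:
            raise ValueError(f"unknown residue symbol {aa!r} in {protein_id!r}")
    if not counted:
        raise ValueError(f"peptide for {protein_id!r} has no scorable residues")
    n = len(counted)
    vf = 100.0 * sum(aa in VF_RESIDUES for aa in counted) / n
    mf = 100.0 * sum(aa in MF_RESIDUES for aa in counted) / n
    return FlexibilityProfile(
        protein_id=protein_id,
        vf_percent=vf,
        mf_percent=mf,
        vmf_percent=vf + mf,
        rigid_percent=100.0 - vf - mf,
    )


def attach_external_classes(
    profiles: Sequence[FlexibilityProfile], m_table: pd.DataFrame
) -> list[FlexibilityProfile]:
    """Attach M0/M1/M2 percentages from an external prediction table.

    ``m_table`` needs columns ``protein_id, m0, m1, m2``; each row must sum
    to 100 within +/-0.5 (rounded inputs are renormalised).  Rows violating
    the invariant, or naming unknown proteins, are logged and skipped.
    Proteins absent from the table keep missing M fields.
    """
    by_id: dict[str, tuple[float, float, float]] = {}
    for row in m_table.itertuples(index=False):
        m0, m1, m2 = float(row.m0), float(row.m1), float(row.m2)
        total = m0 + m1 + m2
        if abs(total - 100.0) > 0.5:
            logger.warning(
                "M-class row for %r sums to %.2f, not 100; skipped",
                row.protein_id, total,
            )
            continue
        by_id[row.protein_id] = (100 * m0 / total, 100 * m1 / total, 100 * m2 / total)

    known = {p.protein_id for p in profiles}
    for pid in set(by_id) - known:
        logger.warning("M-class row for unknown protein %r skipped", pid)

    out = []
    for prof in profiles:
        if prof.protein_id in by_id:
            m0, m1, m2 = by_id[prof.protein_id]
            out.append(
                replace(
                    prof,
                    m0_percent=m0, m1_percent=m1, m2_percent=m2,
                    m12_percent=m1 + m2,
                )
            )
        else:
            out.append(prof)
    return out


def _metric_value(prof: FlexibilityProfile, metric: str) -> float | None:
    if metric == "Vf":
        return prof.vf_percent
    if metric == "VMf":
        return prof.vmf_percent
    if metric == "M2":
        return prof.m2_percent
    if metric == "M1+2":
        return prof.m12_percent
    raise ValueError(f"unknown metric {metric!r}")


def aggregate_by_pathway(
    profiles: Mapping[str, Sequence[FlexibilityProfile]],
    cds_records: Mapping[str, Sequence[CdsRecord]],
) -> pd.DataFrame:
    """Long-format table (species, pathway, metric, protein_id, value).

    A protein with k pathway labels contributes to all k pathway groups and
    once to the ``global`` pseudo-pathway.  The M2 / M1+2 metrics appear
    only for proteins carrying attached external classes.
    """
    rows = []
    for species, profs in profiles.items():
        pathways_of = {
            c.cds_id: c.pathway_labels for c in cds_records.get(species, [])
        }
        for prof in profs:
            groups = [GLOBAL_PATHWAY, *sorted(pathways_of.get(prof.protein_id, ()))]
            for metric in (*COMPOSITION_METRICS, *EXTERNAL_METRICS):
                value = _metric_value(prof, metric)
                if value is None:
                    continue
                for pathway in groups:
                    rows.append(
                        {
                            "species": species,
                            "pathway": pathway,
                            "metric": metric,
                            "protein_id": prof.protein_id,
                            "value": value,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["species", "pathway", "metric", "protein_id", "value"]
    )


def profile_table(profiles: Sequence[FlexibilityProfile]) -> pd.DataFrame:
    """Per-protein profiles as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "vf_percent": p.vf_percent,
                "mf_percent": p.mf_percent,
                "vmf_percent": p.vmf_percent,
                "rigid_percent": p.rigid_percent,
                "m0_percent": p.m0_percent,
                "m1_percent": p.m1_percent,
                "m2_percent": p.m2_percent,
                "m12_percent": p.m12_percent,
            }
            for p in profiles
        ]
    )
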
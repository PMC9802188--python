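"""Pathway completeness scoring and presence calling.

For each MAG that passed the key-enzyme screen, observed pathway completeness
is the detected fraction of the pathway's reaction set (C_obs = 100 |D| / N).
Dividing by genome completeness corrects for MAG incompleteness
(C_adj = min(100, 100 C_obs / C_gen); the uncapped value is retained in the
evidence log).  A pathway is called present when the key gate passed, every
carboxylation key reaction was detected, and the adjusted completeness
reaches the pathway's calibrated threshold (>=, so a threshold derived as
reference-minus-margin passes at equality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import PathwayCatalog, PathwayDefinition
from .qc import MagRecord
from .search import MagDetections, SearchHit

#: Adjusted completeness within this many points below threshold marks a
#: near-miss (reported absent, flagged for manual follow-up).
NEAR_MISS_MARGIN_PP = 5.0


class CallerError(ValueError):
    pass


@dataclass
class PathwayCall:
    mag_id: str
    pathway_id: str
    key_enzyme_pass: bool
    detected_reactions: set[str]
    observed_completeness_pct: float
    genome_completeness_pct: float
    adjusted_completeness_pct: float
    adjusted_uncapped_pct: float
    carboxylation_complete: bool
    present: bool
    near_miss: bool = False
    threshold_pct: float = float("nan")
    evidence: list[SearchHit] = field(default_factory=list)


@dataclass
class CohortSummary:
    n_mags_with_any_cfp: int
    per_pathway_counts: dict[str, int]
    multi_pathway_mags: list[tuple[str, tuple[str, ...]]]


def observed_completeness(detected: set[str], pathway: PathwayDefinition) -> float:
    """Percentage of the pathway's expected reactions that were detected,
    reported to 0.1 pp."""
    foreign = detected - set(pathway.reaction_ids)
    if foreign:
        raise CallerError(
            f"pathway {pathway.pathway_id!r}: unknown reaction id(s) "
            f"{sorted(foreign)}"
        )
    return round(100.0 * len(detected) / pathway.n_reactions_expected, 1)


def adjusted_completeness(observed_pct: float, genome_pct: float) -> float:
    """Observed completeness divided by genome completeness, capped at 100."""
    if genome_pct <= 0:
        raise CallerError(f"genome completeness must be > 0, got {genome_pct}")
    return min(100.0, 100.0 * observed_pct / genome_pct)


def call_pathways(
    mag: MagRecord,
    catalog: PathwayCatalog,
    detections: MagDetections,
    threshold_is_inclusive: bool = True,
) -> list[PathwayCall]:
    """Emit one call per pathway for a quality-filtered MAG.

    Pathways failing the key-enzyme gate are reported absent without
    completeness scoring, mirroring the two-stage screen.
    """
    if mag.genome_completeness_pct is None:
        raise CallerError(f"MAG {mag.mag_id!r}: genome completeness not set")
    genome_pct = mag.genome_completeness_pct
    calls: list[PathwayCall] = []
    for pathway in catalog.pathways:
        pid = pathway.pathway_id
        key_ok = detections.key_pass.get(pid, False)
        if not key_ok:
            calls.append(
                PathwayCall(
                    mag_id=mag.mag_id,
                    pathway_id=pid,
                    key_enzyme_pass=False,
                    detected_reactions=set(),
                    observed_completeness_pct=0.0,
                    genome_completeness_pct=genome_pct,
                    adjusted_completeness_pct=0.0,
                    adjusted_uncapped_pct=0.0,
                    carboxylation_complete=False,
                    present=False,
                    threshold_pct=pathway.threshold_pct,
                )
            )
            continue
        detected = set(detections.reactions.get(pid, set()))
        obs = observed_completeness(detected, pathway)
        uncapped = 100.0 * obs / genome_pct
        adj = adjusted_completeness(obs, genome_pct)
        carbox_ok = set(pathway.carboxylation_ids) <= detected
        if threshold_is_inclusive:
            over = adj >= pathway.threshold_pct
        else:
            over = adj > pathway.threshold_pct
        present = key_ok and carbox_ok and over
        near_miss = (
            key_ok
            and carbox_ok
            and not present
            and adj >= pathway.threshold_pct - NEAR_MISS_MARGIN_PP
        )
        calls.append(
            PathwayCall(
                mag_id=mag.mag_id,
                pathway_id=pid,
                key_enzyme_pass=True,
                detected_reactions=detected,
                observed_completeness_pct=obs,
                genome_completeness_pct=genome_pct,
                adjusted_completeness_pct=adj,
                adjusted_uncapped_pct=uncapped,
                carboxylation_complete=carbox_ok,
                present=present,
                near_miss=near_miss,
                threshold_pct=pathway.threshold_pct,
                evidence=list(detections.key_hits.get(pid, []))
                + list(detections.reaction_hits.get(pid, {}).values()),
            )
        )
    return calls


def _collapse_rtca(pathway_ids: set[str]) -> tuple[str, ...]:
    """The two rTCA citrate-cleavage variants count as one cycle for the
    multi-pathway statistic."""
    units = {("rTCA" if pid in ("rTCA1", "rTCA2") else pid) for pid in pathway_ids}
    return tuple(sorted(units))


def summarize_cohort(
    calls: list[PathwayCall], collapse_rtca: bool = True
) -> CohortSummary:
    """Cohort-level counts: MAGs with any CFP, per-variant counts, and MAGs
    presenting more than one pathway (rTCA1/rTCA2 collapsed by default)."""
    present_by_mag: dict[str, set[str]] = {}
    per_pathway: dict[str, int] = {}
    for call in calls:
        per_pathway.setdefault(call.pathway_id, 0)
        if call.present:
            per_pathway[call.pathway_id] += 1
            present_by_mag.setdefault(call.mag_id, set()).add(call.pathway_id)
    multi: list[tuple[str, tuple[str, ...]]] = []
    for mag_id in sorted(present_by_mag):
        pids = present_by_mag[mag_id]
        units = _collapse_rtca(pids) if collapse_rtca else tuple(sorted(pids))
        if len(units) > 1:
            multi.append((mag_id, tuple(sorted(pids))))
    return CohortSummary(
        n_mags_with_any_cfp=len(present_by_mag),
        per_pathway_counts=per_pathway,
        multi_pathway_mags=multi,
    )
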
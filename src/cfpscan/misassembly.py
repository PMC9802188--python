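"""Mis-assembly screening for singleton pathway calls.

When a taxon is supported by a single MAG, the CFP gene neighborhood is
checked for contamination signals: (1) the GC content of the gene-cluster
span (plus flanks) is compared, as a z-score, against the distribution of GC
over fixed-size windows across the rest of the genome; (2) the genes nearest
the span are assigned source labels by best hit against a labeled reference
collection and compared with the MAG's majority label.  The screen is
advisory — it annotates calls and never revokes them.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .caller import PathwayCall
from .qc import MagRecord
from .search import DEFAULT_BITSCORE_MIN, ProfileSet, ProteinRecord
from .sequences import gc_fraction

DEFAULT_Z_CUTOFF = 2.0
DEFAULT_CONSISTENCY_MIN = 0.5
DEFAULT_FLANK_BP = 5000
DEFAULT_WINDOW_BP = 1000
DEFAULT_K_NEIGHBORS = 10

#: Prefilter word size for best-hit labeling against large reference
#: panels: labels only need near-identical matches, so a longer exact
#: word keeps candidate lists short.
PANEL_PREFILTER_K = 7


class MisassemblyError(ValueError):
    pass


@dataclass
class MisassemblyFlag:
    mag_id: str
    pathway_id: str
    contig_id: str
    span: tuple[int, int]
    gc_zscore: float
    neighbor_consistency: float
    flagged: bool
    reasons: list[str] = field(default_factory=list)


def find_singletons(
    calls: list[PathwayCall], taxon_labels: dict[str, str]
) -> list[tuple[str, str, str]]:
    """(taxon, pathway_id, mag_id) triples where exactly one MAG of the taxon
    carries the pathway.  Unlabeled MAGs group under 'unlabeled'."""
    groups: dict[tuple[str, str], list[str]] = {}
    for call in calls:
        if not call.present:
            continue
        taxon = taxon_labels.get(call.mag_id, "unlabeled")
        groups.setdefault((taxon, call.pathway_id), []).append(call.mag_id)
    return sorted(
        (taxon, pid, mags[0])
        for (taxon, pid), mags in groups.items()
        if len(mags) == 1
    )


def gc_flank_check(
    contigs: dict[str, str],
    span: tuple[str, int, int],
    flank_bp: int = DEFAULT_FLANK_BP,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> float:
    """z-score of the span (+flanks) GC against genome-wide window GC.

    The span is 0-based half-open on its contig, extended by up to flank_bp
    on each side; windows overlapping the extended span are excluded from
    the background.
    """
    contig_id, start, end = span
    if contig_id not in contigs:
        raise MisassemblyError(f"span contig {contig_id!r} not in MAG contigs")
    contig = contigs[contig_id]
    if not (0 <= start < end <= len(contig)):
        raise MisassemblyError(
            f"span ({start}, {end}) outside contig {contig_id!r} "
            f"of length {len(contig)}"
        )
    lo = max(0, start - flank_bp)
    hi = min(len(contig), end + flank_bp)
    span_gc = gc_fraction(contig[lo:hi])

    window_gc: list[float] = []
    for cid, seq in contigs.items():
        if len(seq) < window_bp:
            warnings.warn(
                f"contig {cid!r} shorter than window ({len(seq)} < {window_bp}); skipped"
            )
            continue
        for w0 in range(0, len(seq) - window_bp + 1, window_bp):
            w1 = w0 + window_bp
            if cid == contig_id and w0 < hi and w1 > lo:
                continue  # exclude the evaluated span itself
            window_gc.append(gc_fraction(seq[w0:w1]))
    if len(window_gc) < 2:
        raise MisassemblyError("not enough background windows for a GC z-score")
    arr = np.asarray(window_gc)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return float((span_gc - arr.mean()) / sd)


def best_hit_labels(
    mag: MagRecord,
    reference: list[tuple[str, str, str]],  # (ref_id, source_label, sequence)
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
    pset: ProfileSet | None = None,
) -> dict[str, str]:
    """Assign each MAG protein the source label of its best reference hit.

    Proteins with no hit above the bit-score floor are left unassigned
    (treated as unhittable downstream).  A prebuilt ``pset`` over the
    reference avoids re-indexing when many MAGs are screened.
    """
    if not reference:
        return {}
    labels = {ref_id: label for ref_id, label, _ in reference}
    if pset is None:
        pset = ProfileSet.from_sequences(
            {rid: (seq,) for rid, _, seq in reference}, k=PANEL_PREFILTER_K
        )
    hits = pset.scan(mag.proteins, with_evalue=False)
    best: dict[str, tuple[float, str]] = {}
    for ref_id, hit_list in hits.items():
        for h in hit_list:
            if h.bit_score > bitscore_min:
                cur = best.get(h.protein_id)
                if cur is None or h.bit_score > cur[0]:
                    best[h.protein_id] = (h.bit_score, labels[ref_id])
    return {pid: label for pid, (_, label) in best.items()}


def neighbor_consistency(
    mag: MagRecord,
    span: tuple[str, int, int],
    reference_labels: dict[str, str],
    k: int = DEFAULT_K_NEIGHBORS,
) -> float:
    """Fraction of the k genes nearest the span whose source label matches
    the MAG's majority label.

    Genes without a label (unhittable) are excluded from the denominator;
    with no evaluable neighbor the score is 1.0 (no evidence against).
    """
    contig_id, start, end = span
    located = [p for p in mag.proteins if p.start is not None]
    if not located:
        raise MisassemblyError(
            f"MAG {mag.mag_id!r} has no gene coordinates; provide a GFF3"
        )
    majority_pool = [
        reference_labels[p.protein_id]
        for p in located
        if p.protein_id in reference_labels
    ]
    if not majority_pool:
        return 1.0
    majority = Counter(majority_pool).most_common(1)[0][0]

    def distance(p: ProteinRecord) -> int:
        if p.end <= start:
            return start - p.end
        if p.start >= end:
            return p.start - end
        return -1  # overlaps the span

    on_contig = [p for p in located if p.contig_id == contig_id]
    neighbors = sorted(
        (p for p in on_contig if distance(p) >= 0), key=distance
    )[:k]
    labeled = [
        reference_labels[p.protein_id]
        for p in neighbors
        if p.protein_id in reference_labels
    ]
    if not labeled:
        return 1.0
    return sum(1 for lab in labeled if lab == majority) / len(labeled)


def _call_span(mag: MagRecord, call: PathwayCall) -> tuple[str, int, int] | None:
    """Smallest interval covering the detected CFP genes on the contig that
    carries most of them."""
    pids = {h.protein_id for h in call.evidence}
    genes = [
        p for p in mag.proteins
        if p.protein_id in pids and p.contig_id is not None and p.start is not None
    ]
    if not genes:
        return None
    by_contig = Counter(g.contig_id for g in genes)
    contig_id = by_contig.most_common(1)[0][0]
    on_contig = [g for g in genes if g.contig_id == contig_id]
    return (contig_id, min(g.start for g in on_contig), max(g.end for g in on_contig))


def screen_singletons(
    cohort: list[MagRecord],
    calls: list[PathwayCall],
    taxon_labels: dict[str, str],
    reference: list[tuple[str, str, str]] | None = None,
    reference_labels: dict[str, dict[str, str]] | None = None,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    consistency_min: float = DEFAULT_CONSISTENCY_MIN,
    flank_bp: int = DEFAULT_FLANK_BP,
    window_bp: int = DEFAULT_WINDOW_BP,
    k: int = DEFAULT_K_NEIGHBORS,
) -> list[MisassemblyFlag]:
    """Screen every singleton (taxon, pathway) call for mis-assembly signals.

    Per-protein source labels come either from precomputed per-MAG maps
    (``reference_labels``) or from best-hit assignment against a labeled
    reference collection (``reference``).
    """
    by_id = {m.mag_id: m for m in cohort}
    call_index = {(c.mag_id, c.pathway_id): c for c in calls}
    flags: list[MisassemblyFlag] = []
    label_cache: dict[str, dict[str, str]] = {}
    panel_pset = (
        ProfileSet.from_sequences(
            {rid: (seq,) for rid, _, seq in reference}, k=PANEL_PREFILTER_K
        )
        if reference
        else None
    )
    for taxon, pathway_id, mag_id in find_singletons(calls, taxon_labels):
        mag = by_id[mag_id]
        call = call_index[(mag_id, pathway_id)]
        span = _call_span(mag, call)
        if span is None or mag.contigs is None:
            continue
        z = gc_flank_check(mag.contigs, span, flank_bp=flank_bp, window_bp=window_bp)
        if reference_labels is not None and mag_id in reference_labels:
            labels = reference_labels[mag_id]
        elif reference is not None:
            if mag_id not in label_cache:
                label_cache[mag_id] = best_hit_labels(mag, reference, pset=panel_pset)
            labels = label_cache[mag_id]
        else:
            labels = {}
        consistency = neighbor_consistency(mag, span, labels, k=k) if labels else 1.0
        reasons = []
        if abs(z) > z_cutoff:
            reasons.append(f"flank GC z-score {z:.2f} beyond +/-{z_cutoff}")
        if consistency < consistency_min:
            reasons.append(
                f"neighbor label consistency {consistency:.2f} below {consistency_min}"
            )
        flags.append(
            MisassemblyFlag(
                mag_id=mag_id,
                pathway_id=pathway_id,
                contig_id=span[0],
                span=(span[1], span[2]),
                gc_zscore=z,
                neighbor_consistency=consistency,
                flagged=bool(reasons),
                reasons=reasons,
            )
        )
    return flags
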
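"""MAG input and genome quality control.

Genome completeness is estimated from single-copy marker detection, in the
spirit of lineage-aware marker-set tools: completeness is the fraction of the
domain marker set detected at least once, contamination the fraction detected
in extra copies.  The shipped marker families are synthetic single-copy
fixtures sized to the 120-bacterial / 122-archaeal convention; externally
computed quality tables can be imported instead, bypassing estimation.

MAGs below the completeness floor (default 75%, inclusive-keep at exactly 75)
are excluded from pathway calling unless explicitly overridden; overrides are
recorded in the MAG's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .search import DEFAULT_BITSCORE_MIN, ProfileSet, ProteinRecord
from .sequences import synthetic_protein

N_BACTERIAL_MARKERS = 120
N_ARCHAEAL_MARKERS = 122

DEFAULT_MIN_COMPLETENESS = 75.0


class QcError(ValueError):
    pass


@dataclass
class MagRecord:
    mag_id: str
    proteins: list[ProteinRecord]
    domain_label: str = "unknown"  # bacteria | archaea | unknown
    contigs: dict[str, str] | None = None
    genome_completeness_pct: float | None = None
    contamination_pct: float | None = None
    taxon_label: str | None = None
    provenance: list[str] = dc_field(default_factory=list)


@dataclass(frozen=True)
class MarkerSet:
    domain_label: str
    markers: tuple[tuple[str, str], ...]  # (marker_name, reference sequence)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def default_marker_sets() -> dict[str, MarkerSet]:
    """Synthetic single-copy marker families for both domains.

    Marker reference sequences are deterministic stand-ins (150-250 aa),
    generated from stable keys; only the completeness/contamination numbers
    feed the downstream pipeline.
    """
    bac = tuple(
        (f"bac120_{i:03d}", synthetic_protein(f"marker/bac120_{i:03d}"))
        for i in range(1, N_BACTERIAL_MARKERS + 1)
    )
    arc = tuple(
        (f"ar122_{i:03d}", synthetic_protein(f"marker/ar122_{i:03d}"))
        for i in range(1, N_ARCHAEAL_MARKERS + 1)
    )
    return {
        "bacteria": MarkerSet(domain_label="bacteria", markers=bac),
        "archaea": MarkerSet(domain_label="archaea", markers=arc),
    }


# ---------------------------------------------------------------------------
# Reading MAGs


def _parse_protein_header(header: str, mag_id: str) -> str:
    """Header convention '<mag_id>|<protein_id>'; plain ids pass through."""
    if "|" in header:
        prefix, pid = header.split("|", 1)
        return pid if prefix == mag_id else header
    return header


def _read_gff3(path: Path) -> pd.DataFrame:
    names = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=names, header=None, dtype={"seqid": str}
    )
    df = df[df["type"].isin(["CDS", "gene"])].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    return df


def read_mag(
    protein_fasta: str | Path,
    mag_id: str,
    nucleotide_fasta: str | Path | None = None,
    gff: str | Path | None = None,
    domain_label: str = "unknown",
) -> MagRecord:
    """Load a MAG from FASTA (+ optional contigs and GFF3 coordinates).

    GFF3 coordinates are 1-based inclusive on disk and converted to 0-based
    half-open internally.  Every GFF3 gene must have a matching protein.
    """
    raw = {
        _parse_protein_header(rec.id, mag_id): str(rec.seq).rstrip("*")
        for rec in SeqIO.parse(str(protein_fasta), "fasta")
    }
    contigs = None
    if nucleotide_fasta is not None:
        contigs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(nucleotide_fasta), "fasta")
        }
    coords: dict[str, tuple[str, int, int, str]] = {}
    if gff is not None:
        table = _read_gff3(Path(gff))
        orphans = sorted(set(table["gene_id"]) - set(raw))
        if orphans:
            raise QcError(
                f"MAG {mag_id!r}: GFF3 genes with no protein record: "
                + ", ".join(orphans[:10])
            )
        for row in table.itertuples():
            coords[row.gene_id] = (
                str(row.seqid),
                int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                int(row.end),
                str(row.strand),
            )
    proteins = []
    for pid, seq in raw.items():
        contig_id, start, end, strand = coords.get(pid, (None, None, None, None))
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                mag_id=mag_id,
                sequence=seq,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return MagRecord(
        mag_id=mag_id, proteins=proteins, domain_label=domain_label, contigs=contigs
    )


# ---------------------------------------------------------------------------
# Completeness estimation


def _marker_scan(
    mag: MagRecord, markers: MarkerSet, bitscore_min: float
) -> tuple[float, float]:
    if markers.n_markers == 0:
        raise QcError("empty marker set")
    if not mag.proteins:
        return 0.0, 0.0
    pset = ProfileSet.from_sequences({name: (seq,) for name, seq in markers.markers})
    hits = pset.scan(mag.proteins, with_evalue=False)
    detected = 0
    extra = 0
    for name in pset.profiles:
        copies = sum(1 for h in hits[name] if h.bit_score > bitscore_min)
        if copies >= 1:
            detected += 1
            extra += copies - 1
    return (
        100.0 * detected / markers.n_markers,
        100.0 * extra / markers.n_markers,
    )


def estimate_completeness(
    mag: MagRecord,
    markers: MarkerSet | dict[str, MarkerSet] | None = None,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
) -> tuple[float, float]:
    """Estimate (completeness_pct, contamination_pct) from marker detection.

    With a marker-set mapping and an unknown domain label, both domain sets
    are scanned and the higher-completeness one is used (mirrors
    lineage-specific marker choice).  The estimate is stored on the record.
    """
    if markers is None:
        markers = default_marker_sets()
    if isinstance(markers, MarkerSet):
        chosen = markers
        result = _marker_scan(mag, chosen, bitscore_min)
    else:
        if mag.domain_label in markers:
            chosen = markers[mag.domain_label]
            result = _marker_scan(mag, chosen, bitscore_min)
        else:
            scored = {
                label: _marker_scan(mag, mset, bitscore_min)
                for label, mset in markers.items()
            }
            label = max(sorted(scored), key=lambda k: scored[k][0])
            chosen, result = markers[label], scored[label]
            mag.provenance.append(f"domain auto-selected as {label!r} by marker yield")
    mag.genome_completeness_pct, mag.contamination_pct = result
    return result


def import_qc_table(path: str | Path, cohort: list[MagRecord]) -> None:
    """Attach externally computed completeness/contamination (TSV columns:
    mag_id, completeness, contamination), bypassing estimation."""
    table = pd.read_csv(path, sep="\t")
    required = {"mag_id", "completeness", "contamination"}
    missing = required - set(table.columns)
    if missing:
        raise QcError(f"QC table missing columns: {sorted(missing)}")
    by_id = {m.mag_id: m for m in cohort}
    for row in table.itertuples():
        mag = by_id.get(str(row.mag_id))
        if mag is None:
            continue
        mag.genome_completeness_pct = float(row.completeness)
        mag.contamination_pct = float(row.contamination)
        mag.provenance.append("quality imported from external table")


# ---------------------------------------------------------------------------
# Cohort filter


def filter_mags(
    cohort: list[MagRecord],
    min_completeness_pct: float = DEFAULT_MIN_COMPLETENESS,
    overrides: set[str] | None = None,
) -> tuple[list[MagRecord], list[MagRecord]]:
    """Partition a cohort into (kept, excluded) by the completeness floor.

    Keeps MAGs at exactly the floor (only strictly lower completeness is
    dropped).  Override ids are kept regardless, with a provenance note.
    """
    import warnings

    overrides = set(overrides or ())
    known = {m.mag_id for m in cohort}
    for missing in sorted(overrides - known):
        warnings.warn(f"override MAG id {missing!r} not in cohort")
    kept: list[MagRecord] = []
    excluded: list[MagRecord] = []
    for mag in cohort:
        if mag.genome_completeness_pct is None:
            raise QcError(
                f"MAG {mag.mag_id!r}: completeness not estimated before filtering"
            )
        if mag.genome_completeness_pct >= min_completeness_pct:
            kept.append(mag)
        elif mag.mag_id in overrides:
            mag.provenance.append(
                f"kept by manual override at completeness "
                f"{mag.genome_completeness_pct:.1f}%"
            )
            kept.append(mag)
        else:
            excluded.append(mag)
    return kept, excluded
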
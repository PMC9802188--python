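"""Seeded synthetic MAG cohorts with ground truth.

This generator is the offline stand-in for a real MAG catalogue: it implants
pathway enzymes (mutated copies of the catalog reference sequences) at a
controlled reaction retention and sequence identity, subsamples single-copy
markers to set the true genome completeness, pads the proteome with decoys,
and can add a foreign-GC contaminant contig carrying a full pathway with
foreign labels.  Every draw derives from the cohort seed, so a fixed seed
reproduces the cohort byte for byte.

Deliberate simplifications: substitutions only (the scorer is ungapped),
background genes are random sequences at the genome GC (the neighborhood
screens need realistic nulls, not biology), and protein sequences are not
literal translations of the nucleotide genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog, PathwayDefinition
from .qc import MagRecord, MarkerSet, default_marker_sets
from .search import ProteinRecord
from .sequences import mutate_protein, random_dna, random_protein, shuffle_protein


@dataclass(frozen=True)
class ContaminationSpec:
    insert_pathway_id: str
    foreign_gc: float = 0.65
    foreign_label: str = "foreign"
    insert_identity: float = 0.95
    n_foreign_background: int = 10


@dataclass
class MagSpec:
    mag_id: str
    domain_label: str = "bacteria"
    #: pathway_id -> reaction retention in [0, 1].
    implanted_pathways: dict[str, float] = field(default_factory=dict)
    enzyme_identity_target: float = 1.0
    marker_retention: float = 1.0
    n_decoys: int = 20
    decoy_mode: str = "shuffled"  # shuffled | random
    contamination: ContaminationSpec | None = None
    genome_gc: float = 0.42
    taxon_label: str | None = None
    #: Optional exact drop list per pathway (overrides retention sampling).
    forced_missing: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: Drop non-carboxylation reactions first when retention < 1.
    retain_carboxylation_last: bool = True

    def __post_init__(self) -> None:
        for pid, r in self.implanted_pathways.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{self.mag_id}: retention for {pid} outside [0,1]: {r}")
        if not 0.0 <= self.marker_retention <= 1.0:
            raise ValueError(f"{self.mag_id}: marker_retention outside [0,1]")
        if not 0.0 <= self.enzyme_identity_target <= 1.0:
            raise ValueError(f"{self.mag_id}: enzyme_identity_target outside [0,1]")


@dataclass
class SyntheticCohortSpec:
    seed: int
    mags: list[MagSpec]

    @property
    def n_mags(self) -> int:
        return len(self.mags)


@dataclass
class TruthRow:
    mag_id: str
    true_pathways: tuple[str, ...]
    retained_reactions: dict[str, tuple[str, ...]]
    genome_completeness_pct: float
    contaminated: bool
    contaminant_pathway: str | None = None


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def row(self, mag_id: str) -> TruthRow:
        for r in self.rows:
            if r.mag_id == mag_id:
                return r
        raise KeyError(mag_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mag_id": r.mag_id,
                    "true_pathways": ";".join(r.true_pathways),
                    "genome_completeness_pct": r.genome_completeness_pct,
                    "contaminated": r.contaminated,
                    "contaminant_pathway": r.contaminant_pathway or "",
                }
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# Reaction subset sampling


def _choose_retained(
    pathway: PathwayDefinition,
    retention: float,
    forced_missing: tuple[str, ...] | None,
    carbox_last: bool,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    all_ids = list(pathway.reaction_ids)
    if forced_missing is not None:
        missing = set(forced_missing)
        unknown = missing - set(all_ids)
        if unknown:
            raise ValueError(
                f"{pathway.pathway_id}: forced_missing ids not in pathway: {sorted(unknown)}"
            )
        return tuple(r for r in all_ids if r not in missing)
    n_keep = int(round(retention * len(all_ids)))
    n_drop = len(all_ids) - n_keep
    if n_drop == 0:
        return tuple(all_ids)
    if carbox_last:
        carbox = set(pathway.carboxylation_ids)
        droppable = [r for r in all_ids if r not in carbox]
        rng.shuffle(droppable)
        drop = set(droppable[:n_drop])
        if len(drop) < n_drop:  # retention so low that carboxylations must go
            rest = [r for r in all_ids if r in carbox]
            rng.shuffle(rest)
            drop |= set(rest[: n_drop - len(drop)])
    else:
        pool = list(all_ids)
        rng.shuffle(pool)
        drop = set(pool[:n_drop])
    return tuple(r for r in all_ids if r not in drop)


# ---------------------------------------------------------------------------
# Per-MAG generation


@dataclass
class GeneratedMag:
    record: MagRecord
    truth: TruthRow
    #: protein_id -> true source label (native taxon or foreign label).
    source_labels: dict[str, str]
    #: (ref_id, label, sequence) entries this MAG contributes to the cohort's
    #: labeled reference panel (background/marker/foreign genes; implanted
    #: CFP enzymes are excluded, as their real-world provenance is the
    #: catalog, not a labeled genome).
    panel: list[tuple[str, str, str]]


def generate_mag(
    spec: MagSpec,
    catalog: PathwayCatalog,
    markers: dict[str, MarkerSet] | None = None,
    rng: np.random.Generator | None = None,
) -> GeneratedMag:
    if markers is None:
        markers = default_marker_sets()
    if rng is None:
        rng = np.random.default_rng(0)
    marker_set = markers.get(spec.domain_label) or markers["bacteria"]
    taxon = spec.taxon_label or f"taxon_{spec.mag_id}"

    truth_retained: dict[str, tuple[str, ...]] = {}
    true_pathways: list[str] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{spec.mag_id}_g{counter:04d}"

    # Implanted pathway enzymes, kept as one contiguous gene cluster per
    # pathway (CFP genes sit in operon-like neighborhoods in real genomes,
    # and the neighborhood screens rely on a coherent span).
    clusters: list[list[tuple[str, str, str, bool]]] = []
    for pid in sorted(spec.implanted_pathways):
        retention = spec.implanted_pathways[pid]
        pathway = catalog.pathway(pid)
        retained = _choose_retained(
            pathway,
            retention,
            spec.forced_missing.get(pid),
            spec.retain_carboxylation_last,
            rng,
        )
        truth_retained[pid] = retained
        if set(retained) == set(pathway.reaction_ids):
            true_pathways.append(pid)
        cluster = []
        for rid in retained:
            reaction = pathway.reaction(rid)
            _, ref_seq = reaction.reference_sequences[0]
            seq = mutate_protein(ref_seq, spec.enzyme_identity_target, rng)
            cluster.append((next_id(), seq, taxon, False))
        if cluster:
            clusters.append(cluster)

    background: list[tuple[str, str, str, bool]] = []

    # Single-copy markers (near-identical to their references).
    n_markers = int(round(spec.marker_retention * marker_set.n_markers))
    order = rng.permutation(marker_set.n_markers)[:n_markers]
    for i in sorted(order):
        _, ref_seq = marker_set.markers[int(i)]
        background.append((next_id(), mutate_protein(ref_seq, 0.98, rng), taxon, True))

    # Decoys / background genes.
    reference_pool = [
        seq
        for pathway in catalog.pathways
        for reaction in pathway.reactions
        for _, seq in reaction.reference_sequences
    ]
    for _ in range(spec.n_decoys):
        if spec.decoy_mode == "shuffled":
            src = reference_pool[int(rng.integers(len(reference_pool)))]
            seq = shuffle_protein(src, rng)
        elif spec.decoy_mode == "random":
            seq = random_protein(int(rng.integers(180, 321)), rng)
        else:
            raise ValueError(f"unknown decoy_mode {spec.decoy_mode!r}")
        background.append((next_id(), seq, taxon, True))

    # Background order is randomized; each pathway cluster is inserted
    # intact at a random position.
    perm = rng.permutation(len(background))
    genes = [background[int(i)] for i in perm]
    for cluster in clusters:
        pos = int(rng.integers(0, len(genes) + 1))
        genes[pos:pos] = cluster

    # Foreign contaminant contig: a full pathway plus foreign background.
    foreign_genes: list[tuple[str, str, str, bool]] = []
    contaminant = None
    if spec.contamination is not None:
        cont = spec.contamination
        contaminant = cont.insert_pathway_id
        pathway = catalog.pathway(cont.insert_pathway_id)
        truth_retained[contaminant] = tuple(pathway.reaction_ids)
        true_pathways.append(contaminant)
        for rid in pathway.reaction_ids:
            _, ref_seq = pathway.reaction(rid).reference_sequences[0]
            seq = mutate_protein(ref_seq, cont.insert_identity, rng)
            foreign_genes.append((next_id(), seq, cont.foreign_label, False))
        for _ in range(cont.n_foreign_background):
            seq = random_protein(int(rng.integers(180, 321)), rng)
            foreign_genes.append((next_id(), seq, cont.foreign_label, True))
        fperm = rng.permutation(len(foreign_genes))
        foreign_genes = [foreign_genes[int(i)] for i in fperm]

    # Lay genes onto contigs (nucleotide coordinates; proteins are not
    # literal translations — the nucleotide layer exists for the GC and
    # neighborhood screens).
    contigs: dict[str, str] = {}
    proteins: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    panel: list[tuple[str, str, str]] = []

    def layout(contig_id: str, gene_list, gc: float) -> None:
        parts: list[str] = []
        cursor = 0
        for protein_id, seq, label, in_panel in gene_list:
            spacer = int(rng.integers(50, 151))
            parts.append(random_dna(spacer, gc, rng))
            cursor += spacer
            gene_len = 3 * len(seq)
            parts.append(random_dna(gene_len, gc, rng))
            start, end = cursor, cursor + gene_len
            cursor = end
            proteins.append(
                ProteinRecord(
                    protein_id=protein_id,
                    mag_id=spec.mag_id,
                    sequence=seq,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                )
            )
            labels[protein_id] = label
            if in_panel:
                panel.append((f"src_{protein_id}", label, seq))
        parts.append(random_dna(int(rng.integers(50, 151)), gc, rng))
        contigs[contig_id] = "".join(parts)

    layout(f"{spec.mag_id}_ctg1", genes, spec.genome_gc)
    if foreign_genes:
        layout(
            f"{spec.mag_id}_ctg_foreign",
            foreign_genes,
            spec.contamination.foreign_gc,
        )
        # Foreign CFP genes do enter the panel: a contaminant's source genome
        # is a real, labeled genome elsewhere in the world.
        for protein_id, seq, label, in_panel in foreign_genes:
            if not in_panel:
                panel.append((f"src_{protein_id}", label, seq))

    record = MagRecord(
        mag_id=spec.mag_id,
        proteins=proteins,
        domain_label=spec.domain_label,
        contigs=contigs,
        taxon_label=taxon,
    )
    truth = TruthRow(
        mag_id=spec.mag_id,
        true_pathways=tuple(sorted(set(true_pathways))),
        retained_reactions=truth_retained,
        genome_completeness_pct=100.0 * n_markers / marker_set.n_markers,
        contaminated=spec.contamination is not None,
        contaminant_pathway=contaminant,
    )
    return GeneratedMag(record=record, truth=truth, source_labels=labels, panel=panel)


# ---------------------------------------------------------------------------
# Reference fixtures and cohorts


def generate_reference_fixture(
    pathway_id: str,
    catalog: PathwayCatalog,
    markers: dict[str, MarkerSet] | None = None,
    domain_label: str = "bacteria",
) -> MagRecord:
    """A complete 'reference genome' MAG: verbatim reference enzymes for every
    pathway reaction plus a full, verbatim marker set.  The pipeline scores
    this fixture at observed = adjusted = 100%."""
    if markers is None:
        markers = default_marker_sets()
    marker_set = markers[domain_label]
    pathway = catalog.pathway(pathway_id)
    proteins: list[ProteinRecord] = []
    mag_id = f"ref_{pathway_id}"
    i = 0
    for rid in pathway.reaction_ids:
        _, seq = pathway.reaction(rid).reference_sequences[0]
        i += 1
        proteins.append(
            ProteinRecord(protein_id=f"{mag_id}_g{i:04d}", mag_id=mag_id, sequence=seq)
        )
    for _, seq in marker_set.markers:
        i += 1
        proteins.append(
            ProteinRecord(protein_id=f"{mag_id}_g{i:04d}", mag_id=mag_id, sequence=seq)
        )
    return MagRecord(
        mag_id=mag_id,
        proteins=proteins,
        domain_label=domain_label,
        taxon_label=f"reference_{pathway_id}",
    )


def recovery_benchmark_spec(seed: int, n_groups: int = 20) -> SyntheticCohortSpec:
    """The standard recovery benchmark: per group, one clean true positive
    (rotating pathway, identity 0.8-1.0, marker retention 0.8-1.0), one
    decoy-only negative, and one contaminated MAG carrying a foreign-GC
    insert pathway.  Each MAG gets its own taxon, so positives and
    contaminants are singletons for the mis-assembly screen."""
    from .catalog import PATHWAY_IDS

    identities = (0.8, 0.9, 1.0)
    retentions = (0.8, 0.9, 1.0)
    mags: list[MagSpec] = []
    for g in range(n_groups):
        pid = PATHWAY_IDS[g % len(PATHWAY_IDS)]
        mags.append(
            MagSpec(
                mag_id=f"tp{g:02d}",
                implanted_pathways={pid: 1.0},
                enzyme_identity_target=identities[g % 3],
                marker_retention=retentions[(g // 3) % 3],
                n_decoys=20,
                taxon_label=f"family_tp{g:02d}",
            )
        )
        mags.append(
            MagSpec(
                mag_id=f"neg{g:02d}",
                n_decoys=40,
                marker_retention=0.9,
                taxon_label=f"family_neg{g:02d}",
            )
        )
        insert = PATHWAY_IDS[(g + 2) % len(PATHWAY_IDS)]
        mags.append(
            MagSpec(
                mag_id=f"cont{g:02d}",
                n_decoys=20,
                marker_retention=0.9,
                contamination=ContaminationSpec(insert_pathway_id=insert),
                taxon_label=f"family_cont{g:02d}",
            )
        )
    return SyntheticCohortSpec(seed=seed, mags=mags)


@dataclass
class Cohort:
    mags: list[MagRecord]
    truth: TruthTable
    source_labels: dict[str, dict[str, str]]  # mag_id -> protein -> label
    panel: list[tuple[str, str, str]]


def build_cohort(
    spec: SyntheticCohortSpec,
    catalog: PathwayCatalog,
    markers: dict[str, MarkerSet] | None = None,
) -> Cohort:
    """Generate the cohort in memory; deterministic for a fixed spec.seed."""
    if markers is None:
        markers = default_marker_sets()
    mags, rows, labels, panel = [], [], {}, []
    for i, mag_spec in enumerate(spec.mags):
        rng = np.random.default_rng([spec.seed, i])
        gen = generate_mag(mag_spec, catalog, markers, rng)
        mags.append(gen.record)
        rows.append(gen.truth)
        labels[mag_spec.mag_id] = gen.source_labels
        panel.extend(gen.panel)
    return Cohort(mags=mags, truth=TruthTable(rows), source_labels=labels, panel=panel)


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_cohort(
    spec: SyntheticCohortSpec,
    catalog: PathwayCatalog,
    out_dir: str | Path,
    markers: dict[str, MarkerSet] | None = None,
) -> Cohort:
    """Generate a cohort and write it to disk in the formats the pipeline
    consumes: per-MAG protein FASTA, contig FASTA, GFF3, plus a truth TSV
    and the labeled reference panel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(spec, catalog, markers)
    for mag in cohort.mags:
        _write_fasta(
            out_dir / f"{mag.mag_id}.faa",
            [(f"{mag.mag_id}|{p.protein_id}", p.sequence) for p in mag.proteins],
        )
        if mag.contigs:
            _write_fasta(out_dir / f"{mag.mag_id}.fna", sorted(mag.contigs.items()))
        with open(out_dir / f"{mag.mag_id}.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            for p in mag.proteins:
                if p.contig_id is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            p.contig_id,
                            "cfpscan_synth",
                            "CDS",
                            str(p.start + 1),  # 0-based half-open -> 1-based
                            str(p.end),
                            ".",
                            p.strand or "+",
                            "0",
                            f"ID={p.protein_id}",
                        ]
                    )
                    + "\n"
                )
    cohort.truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    _write_fasta(
        out_dir / "reference_panel.fasta",
        [(f"{label}|{rid}", seq) for rid, label, seq in cohort.panel],
    )
    labels_frame = pd.DataFrame(
        [
            {"mag_id": mag_id, "protein_id": pid, "source_label": label}
            for mag_id, mapping in cohort.source_labels.items()
            for pid, label in mapping.items()
        ]
    )
    labels_frame.to_csv(out_dir / "source_labels.tsv", sep="\t", index=False)
    return cohort
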
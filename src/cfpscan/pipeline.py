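"""End-to-end pipeline orchestration and exports.

Stage order: read -> quality estimation -> completeness filter -> key-enzyme
screen -> reaction annotation -> presence calls -> cohort summary ->
optional energy profiling -> optional mis-assembly screen.  All gates live
in the config with the published defaults (E-value 1e-99, bit score 100,
genome-completeness floor 75%, calibration margin 10 pp, energy report
cutoff 75%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog as catalog_mod
from . import energy as energy_mod
from .caller import CohortSummary, PathwayCall, call_pathways, summarize_cohort
from .misassembly import MisassemblyFlag, screen_singletons
from .qc import MagRecord, default_marker_sets, estimate_completeness, filter_mags, read_mag
from .search import detect_pathways

logger = logging.getLogger("cfpscan")


@dataclass
class PipelineConfig:
    catalog_path: str | None = None
    energy_catalog_path: str | None = None
    input_dir: str | None = None
    output_dir: str | None = None
    evalue_cutoff: float = 1e-99
    bitscore_min: float = 100.0
    min_genome_completeness: float = 75.0
    calibration_margin_pp: float = 10.0
    energy_report_cutoff: float = 75.0
    cap_adjusted: bool = True
    collapse_rtca: bool = True
    run_energy: bool = False
    run_misassembly: bool = False
    seed: int = 0
    overrides: list[str] = field(default_factory=list)
    evalue_null: int = 1000

    def __post_init__(self) -> None:
        for name in ("evalue_cutoff", "bitscore_min", "min_genome_completeness",
                     "energy_report_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"gate {name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    kept: list[MagRecord]
    excluded: list[MagRecord]
    calls: list[PathwayCall]
    summary: CohortSummary
    energy_profiles: list = field(default_factory=list)
    misassembly_flags: list[MisassemblyFlag] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mag_id": c.mag_id,
                    "pathway_id": c.pathway_id,
                    "key_enzyme_pass": c.key_enzyme_pass,
                    "n_detected_reactions": len(c.detected_reactions),
                    "detected_reactions": ";".join(sorted(c.detected_reactions)),
                    "observed_completeness_pct": c.observed_completeness_pct,
                    "genome_completeness_pct": c.genome_completeness_pct,
                    "adjusted_completeness_pct": c.adjusted_completeness_pct,
                    "adjusted_uncapped_pct": round(c.adjusted_uncapped_pct, 1),
                    "carboxylation_complete": c.carboxylation_complete,
                    "threshold_pct": c.threshold_pct,
                    "present": c.present,
                    "near_miss": c.near_miss,
                }
                for c in self.calls
            ]
        )


def _load_input_dir(input_dir: Path) -> list[MagRecord]:
    domains: dict[str, tuple[str, str | None]] = {}
    manifest = input_dir / "domains.tsv"
    if manifest.exists():
        table = pd.read_csv(manifest, sep="\t")
        for row in table.itertuples():
            taxon = getattr(row, "taxon", None)
            domains[str(row.mag_id)] = (str(row.domain), taxon)
    mags = []
    for faa in sorted(input_dir.glob("*.faa")):
        mag_id = faa.stem
        fna = input_dir / f"{mag_id}.fna"
        gff = input_dir / f"{mag_id}.gff"
        domain, taxon = domains.get(mag_id, ("unknown", None))
        mag = read_mag(
            faa,
            mag_id=mag_id,
            nucleotide_fasta=fna if fna.exists() else None,
            gff=gff if gff.exists() else None,
            domain_label=domain,
        )
        if taxon:
            mag.taxon_label = str(taxon)
        mags.append(mag)
    return mags


def run_pipeline(
    config: PipelineConfig,
    mags: list[MagRecord] | None = None,
    taxon_labels: dict[str, str] | None = None,
    reference_panel: list[tuple[str, str, str]] | None = None,
) -> PipelineResult:
    """Run every stage on a cohort (from ``config.input_dir`` or in-memory).

    Each stage logs the count surviving its gate; call rows carry the gates
    and catalog version in the output directory's effective config.
    """
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    cat = catalog_mod.load_catalog(config.catalog_path)
    markers = default_marker_sets()
    if mags is None:
        if config.input_dir is None:
            raise ValueError("no input: provide mags or config.input_dir")
        mags = _load_input_dir(Path(config.input_dir))
    note(f"read: {len(mags)} MAGs")

    for mag in mags:
        if mag.genome_completeness_pct is None:
            estimate_completeness(mag, markers, bitscore_min=config.bitscore_min)
    kept, excluded = filter_mags(
        mags, config.min_genome_completeness, set(config.overrides)
    )
    note(
        f"quality filter (>= {config.min_genome_completeness}%): "
        f"{len(kept)} kept, {len(excluded)} excluded"
    )

    calls: list[PathwayCall] = []
    n_key_pass = 0
    for mag in kept:
        det = detect_pathways(
            mag.proteins,
            cat,
            mag_id=mag.mag_id,
            evalue_null=config.evalue_null,
            bitscore_min=config.bitscore_min,
            evalue_cutoff=config.evalue_cutoff,
        )
        if any(det.key_pass.values()):
            n_key_pass += 1
        calls.extend(call_pathways(mag, cat, det))
    note(f"key-enzyme screen (E < {config.evalue_cutoff:g}): {n_key_pass} MAGs with a hit")

    summary = summarize_cohort(calls, collapse_rtca=config.collapse_rtca)
    note(
        f"calls: {summary.n_mags_with_any_cfp} MAGs with a CFP; "
        f"{len(summary.multi_pathway_mags)} multi-pathway"
    )

    energy_profiles = []
    if config.run_energy:
        ecat = energy_mod.load_energy_catalog(config.energy_catalog_path)
        if config.energy_report_cutoff != ecat.report_cutoff_pct:
            ecat = energy_mod.EnergyCatalog(
                compounds=ecat.compounds,
                photosynthesis=ecat.photosynthesis,
                report_cutoff_pct=config.energy_report_cutoff,
                version=ecat.version,
            )
        for mag in kept:
            energy_profiles.append(
                energy_mod.profile_energy(mag, ecat, bitscore_min=config.bitscore_min)
            )
        note(f"energy profiling: {len(energy_profiles)} MAGs scored")

    flags: list[MisassemblyFlag] = []
    if config.run_misassembly:
        labels = taxon_labels or {
            m.mag_id: (m.taxon_label or "unlabeled") for m in kept
        }
        flags = screen_singletons(
            kept, calls, labels, reference=reference_panel
        )
        note(
            f"mis-assembly screen: {len(flags)} singletons checked, "
            f"{sum(f.flagged for f in flags)} flagged"
        )

    result = PipelineResult(
        kept=kept,
        excluded=excluded,
        calls=calls,
        summary=summary,
        energy_profiles=energy_profiles,
        misassembly_flags=flags,
        log=log,
    )
    if config.output_dir is not None:
        _write_outputs(config, cat.version, result)
    return result


def _write_outputs(config: PipelineConfig, catalog_version: str, result: PipelineResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.calls_frame().to_csv(out / "calls.tsv", sep="\t", index=False)
    summary = {
        "n_mags_with_any_cfp": result.summary.n_mags_with_any_cfp,
        "per_pathway_counts": result.summary.per_pathway_counts,
        "multi_pathway_mags": [
            {"mag_id": mag_id, "pathways": list(pids)}
            for mag_id, pids in result.summary.multi_pathway_mags
        ],
        "catalog_version": catalog_version,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if result.energy_profiles:
        rows = []
        for prof in result.energy_profiles:
            for compound, (pathway_id, pct) in sorted(prof.per_compound.items()):
                rows.append(
                    {
                        "mag_id": prof.mag_id,
                        "compound": compound,
                        "best_pathway": pathway_id,
                        "completeness_pct": pct,
                        "reported": compound in prof.reported,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "energy.tsv", sep="\t", index=False)
    if result.misassembly_flags:
        pd.DataFrame(
            [
                {
                    "mag_id": f.mag_id,
                    "pathway_id": f.pathway_id,
                    "contig_id": f.contig_id,
                    "span_start": f.span[0],
                    "span_end": f.span[1],
                    "gc_zscore": round(f.gc_zscore, 3),
                    "neighbor_consistency": round(f.neighbor_consistency, 3),
                    "flagged": f.flagged,
                    "reasons": "; ".join(f.reasons),
                }
                for f in result.misassembly_flags
            ]
        ).to_csv(out / "misassembly.tsv", sep="\t", index=False)
    export_itol_annotations(
        result.calls, result.energy_profiles, out / "itol_annotations.txt"
    )
    config.to_yaml(out / "effective_config.yaml")
    (out / "pipeline.log").write_text("\n".join(result.log) + "\n")


_PATHWAY_COLORS = {
    "rTCA1": "#1b9e77",
    "rTCA2": "#66c2a5",
    "3HP": "#e6ab02",
    "CBB": "#7570b3",
    "HPHB": "#d95f02",
    "DCHB": "#e7298a",
}


def export_itol_annotations(
    calls: list[PathwayCall], energy_profiles: list, path: str | Path
) -> None:
    """Flat per-MAG annotation table loadable as an iTOL dataset: one colored
    field per present pathway, one numeric field per reported compound.  No
    tree is computed."""
    reported_compounds = sorted(
        {c for prof in energy_profiles for c in prof.reported}
    )
    energy_by_mag = {prof.mag_id: prof for prof in energy_profiles}
    present_by_mag: dict[str, list[PathwayCall]] = {}
    for call in calls:
        if call.present:
            present_by_mag.setdefault(call.mag_id, []).append(call)
    with open(path, "w") as fh:
        fh.write("DATASET_COLORSTRIP\n")
        fh.write("SEPARATOR TAB\n")
        fh.write("DATASET_LABEL\tcarbon fixation pathways\n")
        fh.write(
            "FIELD_LABELS\tpathways\tcolor"
            + "".join(f"\t{c}" for c in reported_compounds)
            + "\n"
        )
        fh.write("DATA\n")
        for mag_id in sorted(present_by_mag):
            mag_calls = present_by_mag[mag_id]
            pids = sorted(c.pathway_id for c in mag_calls)
            color = _PATHWAY_COLORS.get(pids[0], "#999999")
            row = [mag_id, ";".join(pids), color]
            prof = energy_by_mag.get(mag_id)
            for compound in reported_compounds:
                if prof is not None and compound in prof.per_compound:
                    row.append(str(prof.per_compound[compound][1]))
                else:
                    row.append("")
            fh.write("\t".join(row) + "\n")
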
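"""Energy-pathway profiling: inorganic-donor oxidation and pigment synthesis.

For each inorganic electron donor the catalog carries one or more diagnostic
oxidation pathways; a MAG's score for the compound is the completeness of its
MOST complete diagnostic pathway, computed exactly like pathway completeness
but never adjusted by genome completeness.  Compounds whose best pathway
exceeds the report cutoff (strictly greater than 75% by default) make the
reported set.  Photosynthetic potential uses the chlorophyll and
bacteriochlorophyll biosynthesis superpathways under the same rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .qc import MagRecord
from .search import DEFAULT_BITSCORE_MIN, ProfileSet
from .sequences import synthetic_protein


class EnergyCatalogError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyPathway:
    pathway_id: str
    #: (reaction_id, reference sequence) pairs.
    reactions: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class EnergyCatalog:
    compounds: dict[str, tuple[EnergyPathway, ...]]
    photosynthesis: dict[str, EnergyPathway]
    report_cutoff_pct: float = 75.0
    version: str = "1.0"


@dataclass
class EnergyProfile:
    mag_id: str
    per_compound: dict[str, tuple[str, float]]  # compound -> (best pathway, %)
    photosynthesis_pct: dict[str, float]
    reported: set[str]


def _parse_energy_pathway(doc: dict, sidecar: dict[str, str]) -> EnergyPathway:
    reactions = []
    for entry in doc.get("reactions", []):
        rid = str(entry)
        seq = sidecar.get(rid, synthetic_protein(rid))
        reactions.append((rid, seq))
    if not reactions:
        raise EnergyCatalogError(
            f"energy pathway {doc.get('pathway_id')!r} has no reactions"
        )
    return EnergyPathway(pathway_id=str(doc["pathway_id"]), reactions=tuple(reactions))


def load_energy_catalog(path: str | Path | None = None) -> EnergyCatalog:
    if path is None:
        text = resources.files("cfpscan.data").joinpath("energy_catalog.yaml").read_text()
        base_dir = None
    else:
        path = Path(path)
        text = path.read_text()
        base_dir = path.parent
    doc = yaml.safe_load(text)
    sidecar: dict[str, str] = {}
    if doc.get("reference_fasta") and base_dir is not None:
        from Bio import SeqIO

        sidecar = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(base_dir / doc["reference_fasta"]), "fasta")
        }
    compounds: dict[str, tuple[EnergyPathway, ...]] = {}
    for compound, pathways in doc.get("compounds", {}).items():
        if not pathways:
            raise EnergyCatalogError(f"compound {compound!r} has no diagnostic pathways")
        compounds[str(compound)] = tuple(
            _parse_energy_pathway(p, sidecar) for p in pathways
        )
    photosynthesis = {
        str(pigment): _parse_energy_pathway(p, sidecar)
        for pigment, p in doc.get("photosynthesis", {}).items()
    }
    return EnergyCatalog(
        compounds=compounds,
        photosynthesis=photosynthesis,
        report_cutoff_pct=float(doc.get("report_cutoff_pct", 75.0)),
        version=str(doc.get("version", "1.0")),
    )


def _pathway_completeness(
    pathway: EnergyPathway, detected: set[str]
) -> float:
    n = len(pathway.reactions)
    hit = sum(1 for rid, _ in pathway.reactions if rid in detected)
    return round(100.0 * hit / n, 1)


def _detect_reactions(
    mag: MagRecord, catalog: EnergyCatalog, bitscore_min: float
) -> set[str]:
    targets: dict[str, tuple[str, ...]] = {}
    for pathways in catalog.compounds.values():
        for p in pathways:
            for rid, seq in p.reactions:
                targets.setdefault(rid, (seq,))
    for p in catalog.photosynthesis.values():
        for rid, seq in p.reactions:
            targets.setdefault(rid, (seq,))
    if not mag.proteins:
        return set()
    pset = ProfileSet.from_sequences(targets)
    hits = pset.scan(mag.proteins, with_evalue=False)
    return {
        rid for rid, hit_list in hits.items()
        if any(h.bit_score > bitscore_min for h in hit_list)
    }


def profile_energy(
    mag: MagRecord,
    catalog: EnergyCatalog | None = None,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
) -> EnergyProfile:
    """Score all compounds and pigments for one MAG.

    Completeness is never adjusted by genome completeness; the reported set
    uses a strict > cutoff.
    """
    if catalog is None:
        catalog = load_energy_catalog()
    detected = _detect_reactions(mag, catalog, bitscore_min)
    per_compound: dict[str, tuple[str, float]] = {}
    for compound, pathways in catalog.compounds.items():
        scored = [(_pathway_completeness(p, detected), p.pathway_id) for p in pathways]
        best_pct, best_id = max(scored)
        per_compound[compound] = (best_id, best_pct)
    photosynthesis_pct = {
        pigment: _pathway_completeness(p, detected)
        for pigment, p in catalog.photosynthesis.items()
    }
    reported = {
        compound
        for compound, (_, pct) in per_compound.items()
        if pct > catalog.report_cutoff_pct
    }
    return EnergyProfile(
        mag_id=mag.mag_id,
        per_compound=per_compound,
        photosynthesis_pct=photosynthesis_pct,
        reported=reported,
    )


def photosynthesis_potential(
    mag: MagRecord,
    catalog: EnergyCatalog | None = None,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
) -> dict[str, float]:
    """Completeness of the two pigment-biosynthesis superpathways."""
    if catalog is None:
        catalog = load_energy_catalog()
    restricted = EnergyCatalog(
        compounds={},
        photosynthesis=catalog.photosynthesis,
        report_cutoff_pct=catalog.report_cutoff_pct,
        version=catalog.version,
    )
    detected = _detect_reactions(mag, restricted, bitscore_min)
    return {
        pigment: _pathway_completeness(p, detected)
        for pigment, p in catalog.photosynthesis.items()
    }
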
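"""Carbon-fixation pathway (CFP) catalog: definitions, validation, calibration.

The shipped catalog encodes six prokaryotic CFP variants — the two reverse-TCA
citrate-cleavage variants (rTCA1 via ATP-citrate lyase, rTCA2 via citryl-CoA
synthetase + lyase), the 3-hydroxypropionate bi-cycle (3HP), the
Calvin-Benson-Bassham cycle (CBB), and the two 4-hydroxybutyrate cycles
(HP/HB and DC/HB) — each with its reaction set, key screening enzymes,
carboxylation flags, and an expected-completeness presence threshold.

Thresholds are calibrated from complete reference genomes: the threshold is
set a fixed margin (default 10 percentage points) below the completeness the
pipeline observes for the pathway's reference organism.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .sequences import synthetic_protein

#: EC strings accepted by the catalog: full EC, partial EC, or the literal
#: placeholder "1.1.1.co" used for the succinate semialdehyde reductase,
#: which has no official EC assignment.
_EC_PATTERN = re.compile(r"^(\d+\.\d+\.\d+\.\d+|\d+\.\d+\.\d+|1\.1\.1\.co)$")

PATHWAY_IDS = ("rTCA1", "rTCA2", "3HP", "CBB", "HPHB", "DCHB")


class CatalogError(ValueError):
    """Malformed or invalid catalog content."""


@dataclass(frozen=True)
class Reaction:
    """One pathway reaction, detectable through its reference enzymes."""

    reaction_id: str
    ec_number: str
    name: str
    is_carboxylation: bool = False
    #: (accession, amino-acid sequence) pairs; any one hit counts as detection.
    reference_sequences: tuple[tuple[str, str], ...] = ()
    comment: str = ""

    def __post_init__(self) -> None:
        if not _EC_PATTERN.match(self.ec_number):
            raise CatalogError(
                f"reaction {self.reaction_id!r}: bad ec_number {self.ec_number!r}"
            )


@dataclass(frozen=True)
class KeyEnzymeProfile:
    """A key-enzyme search profile used for the E-value pre-screen."""

    enzyme_name: str
    seed_sequences: tuple[str, ...]
    evalue_cutoff: float = 1e-99

    def __post_init__(self) -> None:
        if not self.seed_sequences:
            raise CatalogError(f"key enzyme {self.enzyme_name!r}: no seed sequences")
        if not self.evalue_cutoff > 0:
            raise CatalogError(
                f"key enzyme {self.enzyme_name!r}: cutoff must be > 0"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    reactions: tuple[Reaction, ...]
    n_reactions_expected: int
    key_enzymes: tuple[KeyEnzymeProfile, ...]
    #: Disjunctive key logic: the gate passes if EVERY enzyme of ANY group hits.
    key_logic: tuple[tuple[str, ...], ...]
    threshold_pct: float
    reference_genome: str = ""
    reference_organism: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_pct <= 100:
            raise CatalogError(
                f"pathway {self.pathway_id!r}: threshold_pct {self.threshold_pct} "
                "outside [0, 100]"
            )
        known = {k.enzyme_name for k in self.key_enzymes}
        for group in self.key_logic:
            for name in group:
                if name not in known:
                    raise CatalogError(
                        f"pathway {self.pathway_id!r}: key_logic references "
                        f"unknown enzyme {name!r}"
                    )

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.reaction_id for r in self.reactions)

    @property
    def carboxylation_ids(self) -> tuple[str, ...]:
        return tuple(r.reaction_id for r in self.reactions if r.is_carboxylation)

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise KeyError(reaction_id)


@dataclass(frozen=True)
class PathwayCatalog:
    pathways: tuple[PathwayDefinition, ...]
    calibration_margin_pp: float = 10.0
    version: str = "1.0"

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise CatalogError(f"duplicate pathway_id in catalog: {ids}")
        if self.calibration_margin_pp < 0:
            raise CatalogError("calibration_margin_pp must be >= 0")

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self.pathways)

    def pathway(self, pathway_id: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class ValidationReport:
    issues: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, pathway_id: str, message: str) -> None:
        self.issues.append((pathway_id, message))


# ---------------------------------------------------------------------------
# Loading / saving


def _infer_ec(reaction_id: str) -> str:
    """EC number from a sub-reaction id: strip a single trailing letter when
    the remainder is itself a full EC number (e.g. '2.3.3.8a' -> '2.3.3.8')."""
    if re.match(r"^\d+\.\d+\.\d+\.\d+[a-z]$", reaction_id):
        return reaction_id[:-1]
    return reaction_id


def _resolve_refs(entry: dict, sidecar: dict[str, str]) -> tuple[tuple[str, str], ...]:
    refs = entry.get("refs")
    if refs is None:
        refs = [entry["reaction_id"]]
    out = []
    for ref in refs:
        if isinstance(ref, dict):
            # Embedded sequence: {accession: ..., sequence: ...}
            out.append((str(ref["accession"]), str(ref["sequence"])))
        elif ref in sidecar:
            out.append((str(ref), sidecar[ref]))
        else:
            # Synthetic stand-in generated deterministically from the key.
            out.append((str(ref), synthetic_protein(str(ref))))
    return tuple(out)


def _load_sidecar_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _parse_pathway(doc: dict, sidecar: dict[str, str]) -> PathwayDefinition:
    try:
        pathway_id = doc["pathway_id"]
    except KeyError as exc:
        raise CatalogError("pathway document missing field 'pathway_id'") from exc
    reactions = []
    for entry in doc.get("reactions", []):
        try:
            rid = entry["reaction_id"]
        except KeyError as exc:
            raise CatalogError(
                f"pathway {pathway_id!r}: reaction missing field 'reaction_id'"
            ) from exc
        reactions.append(
            Reaction(
                reaction_id=str(rid),
                ec_number=str(entry.get("ec", _infer_ec(str(rid)))),
                name=str(entry.get("name", "")),
                is_carboxylation=bool(entry.get("carboxylation", False)),
                reference_sequences=_resolve_refs(
                    {**entry, "reaction_id": str(rid)}, sidecar
                ),
                comment=str(entry.get("comment", "")),
            )
        )
    key_enzymes = []
    for entry in doc.get("key_enzymes", []):
        seeds = []
        for ref in entry.get("seed_refs", []):
            seeds.append(sidecar.get(ref, synthetic_protein(str(ref))))
        for seq in entry.get("seed_sequences", []):
            seeds.append(str(seq))
        key_enzymes.append(
            KeyEnzymeProfile(
                enzyme_name=str(entry["enzyme_name"]),
                seed_sequences=tuple(seeds),
                evalue_cutoff=float(entry.get("evalue_cutoff", 1e-99)),
            )
        )
    try:
        threshold = float(doc["threshold_pct"])
        n_expected = int(doc["n_reactions_expected"])
    except KeyError as exc:
        raise CatalogError(
            f"pathway {pathway_id!r}: missing field {exc.args[0]!r}"
        ) from exc
    return PathwayDefinition(
        pathway_id=str(pathway_id),
        name=str(doc.get("name", "")),
        reactions=tuple(reactions),
        n_reactions_expected=n_expected,
        key_enzymes=tuple(key_enzymes),
        key_logic=tuple(tuple(g) for g in doc.get("key_logic", [])),
        threshold_pct=threshold,
        reference_genome=str(doc.get("reference_genome", "")),
        reference_organism=str(doc.get("reference_organism", "")),
        comment=str(doc.get("comment", "")),
    )


def load_catalog(path: str | Path | None = None) -> PathwayCatalog:
    """Load a pathway catalog; the shipped default reproduces the published
    reaction counts and thresholds for the six CFP variants."""
    if path is None:
        source = resources.files("cfpscan.data").joinpath("cfp_catalog.yaml")
        text = source.read_text()
        base_dir = None
    else:
        path = Path(path)
        text = path.read_text()
        base_dir = path.parent
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogError(f"catalog file does not parse as YAML: {exc}") from exc
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise CatalogError("catalog file missing top-level field 'pathways'")
    sidecar: dict[str, str] = {}
    if doc.get("reference_fasta") and base_dir is not None:
        sidecar = _load_sidecar_fasta(base_dir / doc["reference_fasta"])
    pathways = tuple(_parse_pathway(p, sidecar) for p in doc["pathways"])
    return PathwayCatalog(
        pathways=pathways,
        calibration_margin_pp=float(doc.get("calibration_margin_pp", 10.0)),
        version=str(doc.get("version", "1.0")),
    )


def save_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    """Serialise a catalog with reference sequences embedded, so that
    load(save(catalog)) round-trips field-for-field."""
    doc: dict = {
        "version": catalog.version,
        "calibration_margin_pp": catalog.calibration_margin_pp,
        "pathways": [],
    }
    for p in catalog.pathways:
        doc["pathways"].append(
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "reference_genome": p.reference_genome,
                "reference_organism": p.reference_organism,
                "comment": p.comment,
                "n_reactions_expected": p.n_reactions_expected,
                "threshold_pct": p.threshold_pct,
                "key_logic": [list(g) for g in p.key_logic],
                "key_enzymes": [
                    {
                        "enzyme_name": k.enzyme_name,
                        "evalue_cutoff": k.evalue_cutoff,
                        "seed_sequences": list(k.seed_sequences),
                    }
                    for k in p.key_enzymes
                ],
                "reactions": [
                    {
                        "reaction_id": r.reaction_id,
                        "ec": r.ec_number,
                        "name": r.name,
                        "carboxylation": r.is_carboxylation,
                        "comment": r.comment,
                        "refs": [
                            {"accession": acc, "sequence": seq}
                            for acc, seq in r.reference_sequences
                        ],
                    }
                    for r in p.reactions
                ],
            }
        )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Validation / calibration


def validate_catalog(catalog: PathwayCatalog) -> ValidationReport:
    """Report-only consistency checks on a catalog."""
    report = ValidationReport()
    for p in catalog.pathways:
        if len(p.reactions) != p.n_reactions_expected:
            report.add(
                p.pathway_id,
                f"reaction count {len(p.reactions)} != expected "
                f"{p.n_reactions_expected}",
            )
        if not p.carboxylation_ids:
            report.add(p.pathway_id, "no carboxylation reaction flagged")
        for r in p.reactions:
            if not r.reference_sequences:
                report.add(
                    p.pathway_id,
                    f"reaction {r.reaction_id} has no reference sequences",
                )
        if not p.key_enzymes:
            report.add(p.pathway_id, "no key enzymes defined")
        if not p.key_logic:
            report.add(p.pathway_id, "no key-enzyme logic defined")
    return report


def calibrate_thresholds(
    catalog: PathwayCatalog,
    reference_results: dict[str, float],
    margin_pp: float | None = None,
) -> PathwayCatalog:
    """Set each pathway threshold to (reference completeness - margin),
    floored at zero.  The input catalog is not modified."""
    if margin_pp is None:
        margin_pp = catalog.calibration_margin_pp
    missing = [p.pathway_id for p in catalog.pathways if p.pathway_id not in reference_results]
    if missing:
        raise CatalogError(f"no reference result for pathway(s): {', '.join(missing)}")
    new_pathways = []
    for p in catalog.pathways:
        ref = float(reference_results[p.pathway_id])
        if not 0 <= ref <= 100:
            raise CatalogError(
                f"reference result for {p.pathway_id!r} outside [0, 100]: {ref}"
            )
        q = copy.deepcopy(p)
        object.__setattr__(q, "threshold_pct", max(0.0, ref - margin_pp))
        new_pathways.append(q)
    return PathwayCatalog(
        pathways=tuple(new_pathways),
        calibration_margin_pp=float(margin_pp),
        version=catalog.version,
    )
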
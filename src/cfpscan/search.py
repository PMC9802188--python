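"""Native profile search: position-specific scoring with E-value calibration.

The scorer is an ungapped position-specific score matrix (PSSM) search.  A
profile is built from one or more equal-length seed sequences as per-column
log2-odds against background amino-acid frequencies; a protein's bit score is
the best-scoring ungapped placement of the profile along the protein (all
offsets).  Because per-column probabilities sum to one, bit scores admit the
exact Chernoff bound P(S >= s) <= 2^-s under the background null, so E-values
use an extreme-value (Gumbel) calibration with the scale pinned to 1/ln 2 and
only the location estimated from seeded random-sequence maxima.

Two gates mirror standard annotation practice: key-enzyme screening requires
E-value below a strict cutoff (default 1e-99), and pathway-reaction detection
requires a bit score strictly greater than a floor (default 100).
A k-mer prefilter (exact shared 5-mers, BLAST-style seeding) skips hopeless
profile/protein pairs in cohort-scale scans; the underlying scorer is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog import PathwayCatalog
from .sequences import (
    AA_ALPHABET,
    BACKGROUND,
    X_INDEX,
    encode_protein,
    random_protein,
    stable_seed,
)

LN2 = math.log(2.0)

#: Mixing weight of the background in per-column emission probabilities.
PSEUDOCOUNT = 0.1

DEFAULT_EVALUE_CUTOFF = 1e-99
DEFAULT_BITSCORE_MIN = 100.0


class SearchError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with optional contig linkage (0-based half-open)."""

    protein_id: str
    mag_id: str
    sequence: str
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        if self.start is not None and self.end is not None and not self.end > self.start:
            raise ValueError(
                f"protein {self.protein_id!r}: end must exceed start "
                f"({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class SearchHit:
    protein_id: str
    target_id: str
    bit_score: float
    evalue: float
    percent_identity: float = float("nan")
    query_coverage: float = float("nan")


@dataclass(frozen=True)
class NullCalibration:
    """Gumbel location for null maxima; scale fixed at 1/ln 2 bits."""

    loc: float
    scale: float
    calib_len: int
    n_null: int
    seed: int


@dataclass
class Profile:
    """Position-specific log2-odds matrix over the 20-letter alphabet + X."""

    name: str
    seeds: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)  # (ncols, 21); X column scores 0
    consensus: np.ndarray = field(repr=False)
    calibration: NullCalibration | None = None

    @property
    def ncols(self) -> int:
        return self.matrix.shape[0]

    def fingerprint(self) -> int:
        return stable_seed("profile", self.name, *self.seeds)


def build_profile(seed_sequences: list[str] | tuple[str, ...], name: str = "") -> Profile:
    """Build a PSSM from equal-length (gapless pre-aligned) seed sequences.

    Column emission probabilities mix observed residue frequencies with the
    background (weight ``PSEUDOCOUNT``), so duplicate seeds are idempotent.
    """
    seeds = tuple(seed_sequences)
    if not seeds:
        raise SearchError("cannot build a profile from an empty seed list")
    length = len(seeds[0])
    if length == 0:
        raise SearchError("zero-length consensus: seeds are empty")
    if any(len(s) != length for s in seeds):
        raise SearchError(
            "seeds differ in length; provide a gapless alignment "
            f"(got lengths {sorted({len(s) for s in seeds})})"
        )
    counts = np.zeros((length, len(AA_ALPHABET)))
    for seed in seeds:
        idx = encode_protein(seed)
        for col, a in enumerate(idx):
            if a != X_INDEX:
                counts[col, a] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    probs = (1.0 - PSEUDOCOUNT) * freqs + PSEUDOCOUNT * BACKGROUND[None, :]
    matrix = np.zeros((length, len(AA_ALPHABET) + 1))
    matrix[:, : len(AA_ALPHABET)] = np.log2(probs / BACKGROUND[None, :])
    # X / unknown residues are scored as background (0 bits).
    return Profile(
        name=name or f"profile[{len(seeds)}x{length}]",
        seeds=seeds,
        matrix=matrix,
        consensus=matrix[:, : len(AA_ALPHABET)].argmax(axis=1),
    )


def n_offsets(profile_len: int, protein_len: int) -> int:
    return abs(protein_len - profile_len) + 1


def window_scores(profile: Profile, encoded: np.ndarray) -> np.ndarray:
    """Scores of every ungapped placement of profile vs protein.

    When the protein is at least as long as the profile, the profile slides
    fully inside the protein; otherwise the protein slides fully inside the
    profile.
    """
    mat = profile.matrix
    n, L = profile.ncols, encoded.size
    if L >= n:
        windows = np.lib.stride_tricks.sliding_window_view(encoded, n)
        return mat[np.arange(n)[None, :], windows].sum(axis=1)
    cols = np.arange(L)
    return np.array([mat[j + cols, encoded].sum() for j in range(n - L + 1)])


def best_ungapped_score(profile: Profile, sequence: str) -> tuple[float, int]:
    """Maximum bit score over all offsets, and the best offset."""
    scores = window_scores(profile, encode_protein(sequence))
    j = int(scores.argmax())
    return float(scores[j]), j


# ---------------------------------------------------------------------------
# Null calibration and E-values

_CALIBRATION_CACHE: dict[tuple[int, int], NullCalibration] = {}


def calibrate_profile(
    profile: Profile, n_null: int = 1000, calib_len: int | None = None
) -> Profile:
    """Fit the null-score Gumbel location on seeded random sequences.

    Deterministic: the RNG seed derives from the profile content, so the same
    profile always yields the same calibration.  Results are cached.
    """
    if calib_len is None:
        calib_len = profile.ncols + 100
    key = (profile.fingerprint(), n_null)
    calib = _CALIBRATION_CACHE.get(key)
    if calib is None:
        seed = stable_seed("null-calibration", profile.fingerprint(), n_null)
        rng = np.random.default_rng(seed)
        draws = rng.choice(len(AA_ALPHABET), size=(n_null, calib_len), p=BACKGROUND)
        mat = profile.matrix
        n = profile.ncols
        cols = np.arange(n)[None, :]
        w = calib_len - n + 1
        maxima = np.full(n_null, -np.inf)
        for j in range(w):
            np.maximum(maxima, mat[cols, draws[:, j : j + n]].sum(axis=1), out=maxima)
        # Scale is pinned at 1/ln 2 (the Karlin-Altschul value for log2-odds
        # scores); the location anchors the Gumbel median at the empirical
        # median of the null maxima, which is robust and leaves the deep
        # tail governed by the theoretical decay.
        scale = 1.0 / LN2
        loc = float(np.median(maxima)) + scale * math.log(math.log(2.0))
        calib = NullCalibration(
            loc=loc, scale=scale, calib_len=calib_len,
            n_null=n_null, seed=seed,
        )
        _CALIBRATION_CACHE[key] = calib
    profile.calibration = calib
    return profile


def evalue_from_score(profile: Profile, bit_score: float, protein_len: int) -> float:
    """E-value of a bit score: Gumbel tail times the number of offsets.

    The window-count scaling is conservative (a random protein's best score
    maps to an E-value near the offset count, well above 1), which suits the
    strict screening gates this pipeline uses.
    """
    calib = profile.calibration
    if calib is None:
        raise SearchError(
            f"profile {profile.name!r} has no null calibration; call "
            "calibrate_profile first"
        )
    z = (bit_score - calib.loc) / calib.scale
    if z > 30.0:
        sf = math.exp(-z) if z < 745.0 else 0.0
    else:
        sf = float(stats.gumbel_r.sf(z))
    return n_offsets(profile.ncols, protein_len) * sf


def _identity_coverage(profile: Profile, encoded: np.ndarray, offset: int) -> tuple[float, float]:
    n, L = profile.ncols, encoded.size
    if L >= n:
        window = encoded[offset : offset + n]
        matches = int((window == profile.consensus).sum())
        aligned = n
    else:
        matches = int((encoded == profile.consensus[offset : offset + L]).sum())
        aligned = L
    return 100.0 * matches / aligned, 100.0 * aligned / n


def score_protein(profile: Profile, protein: ProteinRecord) -> SearchHit:
    """Score one protein against a calibrated profile."""
    if profile.calibration is None:
        raise SearchError(
            f"profile {profile.name!r} is not calibrated; call calibrate_profile"
        )
    encoded = encode_protein(protein.sequence)
    scores = window_scores(profile, encoded)
    j = int(scores.argmax())
    bit = float(scores[j])
    ident, cov = _identity_coverage(profile, encoded, j)
    return SearchHit(
        protein_id=protein.protein_id,
        target_id=profile.name,
        bit_score=bit,
        evalue=evalue_from_score(profile, bit, len(protein.sequence)),
        percent_identity=ident,
        query_coverage=cov,
    )


# ---------------------------------------------------------------------------
# k-mer prefilter

PREFILTER_K = 5


class KmerIndex:
    """Exact shared-k-mer prefilter over target seed sequences."""

    def __init__(self, targets: dict[str, tuple[str, ...]], k: int = PREFILTER_K):
        self.k = k
        self._index: dict[str, set[str]] = {}
        self._all: set[str] = set(targets)
        for name, seqs in targets.items():
            for seq in seqs:
                for i in range(len(seq) - k + 1):
                    self._index.setdefault(seq[i : i + k], set()).add(name)

    def candidates(self, sequence: str) -> set[str]:
        if len(sequence) < self.k:
            return set(self._all)
        out: set[str] = set()
        for i in range(len(sequence) - self.k + 1):
            hit = self._index.get(sequence[i : i + self.k])
            if hit:
                out |= hit
        return out


# ---------------------------------------------------------------------------
# Profile collections

_PROFILE_CACHE: dict[int, Profile] = {}


def _cached_profile(name: str, seeds: tuple[str, ...]) -> Profile:
    key = stable_seed("profile", name, *seeds)
    prof = _PROFILE_CACHE.get(key)
    if prof is None:
        prof = build_profile(seeds, name=name)
        _PROFILE_CACHE[key] = prof
    return prof


class ProfileSet:
    """A named collection of profiles with a shared k-mer prefilter."""

    def __init__(
        self,
        profiles: dict[str, Profile],
        prefilter: bool = True,
        k: int = PREFILTER_K,
    ):
        self.profiles = profiles
        self.prefilter = prefilter
        self._index = (
            KmerIndex({n: p.seeds for n, p in profiles.items()}, k=k)
            if prefilter
            else None
        )

    @classmethod
    def from_sequences(
        cls,
        targets: dict[str, tuple[str, ...]],
        prefilter: bool = True,
        k: int = PREFILTER_K,
    ) -> "ProfileSet":
        return cls(
            {name: _cached_profile(name, seeds) for name, seeds in targets.items()},
            prefilter=prefilter,
            k=k,
        )

    def calibrate(self, n_null: int = 1000) -> None:
        for prof in self.profiles.values():
            calibrate_profile(prof, n_null=n_null)

    def scan(
        self, proteins: list[ProteinRecord], with_evalue: bool = False
    ) -> dict[str, list[SearchHit]]:
        """All profile/protein scores surviving the prefilter, per target.

        When ``with_evalue`` is false the E-value field is +inf and no null
        calibration is required (bit-score-gated paths).
        """
        hits: dict[str, list[SearchHit]] = {name: [] for name in self.profiles}
        for protein in proteins:
            if self._index is not None:
                names = self._index.candidates(protein.sequence)
            else:
                names = set(self.profiles)
            if not names:
                continue
            encoded = encode_protein(protein.sequence)
            for name in sorted(names):
                prof = self.profiles[name]
                scores = window_scores(prof, encoded)
                j = int(scores.argmax())
                bit = float(scores[j])
                ident, cov = _identity_coverage(prof, encoded, j)
                ev = (
                    evalue_from_score(prof, bit, len(protein.sequence))
                    if with_evalue
                    else float("inf")
                )
                hits[name].append(
                    SearchHit(
                        protein_id=protein.protein_id,
                        target_id=name,
                        bit_score=bit,
                        evalue=ev,
                        percent_identity=ident,
                        query_coverage=cov,
                    )
                )
        return hits


# ---------------------------------------------------------------------------
# Catalog-level operations


@dataclass
class MagDetections:
    """Per-MAG search outcome consumed by the pathway caller."""

    mag_id: str
    key_pass: dict[str, bool]
    key_hits: dict[str, list[SearchHit]]
    reactions: dict[str, set[str]]
    reaction_hits: dict[str, dict[str, SearchHit]]


def _key_profiles(catalog: PathwayCatalog) -> dict[str, Profile]:
    profiles: dict[str, Profile] = {}
    for pathway in catalog.pathways:
        for enzyme in pathway.key_enzymes:
            if enzyme.enzyme_name not in profiles:
                profiles[enzyme.enzyme_name] = _cached_profile(
                    enzyme.enzyme_name, tuple(enzyme.seed_sequences)
                )
    return profiles


def _reaction_targets(catalog: PathwayCatalog) -> dict[str, tuple[str, ...]]:
    """One single-seed target per reaction reference sequence, shared across
    pathways through the accession key."""
    targets: dict[str, tuple[str, ...]] = {}
    for pathway in catalog.pathways:
        for reaction in pathway.reactions:
            for accession, seq in reaction.reference_sequences:
                targets.setdefault(accession, (seq,))
    return targets


def screen_key_enzymes(
    proteins: list[ProteinRecord],
    catalog: PathwayCatalog,
    n_null: int = 1000,
    evalue_cutoff: float | None = None,
) -> tuple[dict[str, bool], dict[str, list[SearchHit]]]:
    """Two-stage screen, stage one: which pathways' key-enzyme logic is
    satisfied by hits passing the per-enzyme E-value cutoff.

    ``evalue_cutoff`` overrides every enzyme's own cutoff when given.
    """
    profiles = _key_profiles(catalog)
    pset = ProfileSet(profiles)
    pset.calibrate(n_null=n_null)
    raw = pset.scan(proteins, with_evalue=True)

    cutoff_by_enzyme = {
        enzyme.enzyme_name: (
            evalue_cutoff if evalue_cutoff is not None else enzyme.evalue_cutoff
        )
        for pathway in catalog.pathways
        for enzyme in pathway.key_enzymes
    }
    passing: dict[str, list[SearchHit]] = {
        name: [h for h in raw[name] if h.evalue < cutoff_by_enzyme[name]]
        for name in profiles
    }
    flags: dict[str, bool] = {}
    support: dict[str, list[SearchHit]] = {}
    for pathway in catalog.pathways:
        ok = any(
            all(passing[name] for name in group) for group in pathway.key_logic
        )
        flags[pathway.pathway_id] = bool(ok)
        support[pathway.pathway_id] = [
            h
            for group in pathway.key_logic
            for name in group
            for h in passing[name]
        ]
    return flags, support


def annotate_reactions(
    proteins: list[ProteinRecord],
    catalog: PathwayCatalog,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
    pathway_ids: list[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, dict[str, SearchHit]]]:
    """Stage two: which reactions of each pathway have a protein scoring
    strictly above the bit-score floor against any reference sequence."""
    wanted = list(pathway_ids) if pathway_ids is not None else list(catalog.pathway_ids)
    targets: dict[str, tuple[str, ...]] = {}
    for pid in wanted:
        for reaction in catalog.pathway(pid).reactions:
            for accession, seq in reaction.reference_sequences:
                targets.setdefault(accession, (seq,))
    pset = ProfileSet.from_sequences(targets)
    raw = pset.scan(proteins, with_evalue=False)
    best: dict[str, SearchHit] = {}
    for name, hit_list in raw.items():
        for h in hit_list:
            if h.bit_score > bitscore_min and (
                name not in best or h.bit_score > best[name].bit_score
            ):
                best[name] = h

    detected: dict[str, set[str]] = {}
    evidence: dict[str, dict[str, SearchHit]] = {}
    for pid in wanted:
        detected[pid] = set()
        evidence[pid] = {}
        for reaction in catalog.pathway(pid).reactions:
            hits = [
                best[acc]
                for acc, _ in reaction.reference_sequences
                if acc in best
            ]
            if hits:
                detected[pid].add(reaction.reaction_id)
                evidence[pid][reaction.reaction_id] = max(
                    hits, key=lambda h: h.bit_score
                )
    return detected, evidence


def detect_pathways(
    proteins: list[ProteinRecord],
    catalog: PathwayCatalog,
    mag_id: str = "",
    evalue_null: int = 1000,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
    evalue_cutoff: float | None = None,
    annotate_all: bool = False,
) -> MagDetections:
    """Run both stages; reactions are only annotated for pathways whose key
    gate passed (the two-stage screen), unless ``annotate_all``."""
    flags, support = screen_key_enzymes(
        proteins, catalog, n_null=evalue_null, evalue_cutoff=evalue_cutoff
    )
    wanted = [pid for pid in catalog.pathway_ids if annotate_all or flags[pid]]
    reactions: dict[str, set[str]] = {pid: set() for pid in catalog.pathway_ids}
    evidence: dict[str, dict[str, SearchHit]] = {pid: {} for pid in catalog.pathway_ids}
    if wanted:
        det, ev = annotate_reactions(
            proteins, catalog, bitscore_min=bitscore_min, pathway_ids=wanted
        )
        reactions.update(det)
        evidence.update(ev)
    return MagDetections(
        mag_id=mag_id,
        key_pass=flags,
        key_hits=support,
        reactions=reactions,
        reaction_hits=evidence,
    )


# ---------------------------------------------------------------------------
# Hit import/export (bridge to external search tools)

HITS_COLUMNS = ("protein_id", "target_id", "bit_score", "evalue")


def export_hits(path, key_hits_raw: list[SearchHit], reaction_hits_raw: list[SearchHit]) -> None:
    """Write ungated hits as the four-column TSV ``import_hits`` consumes."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HITS_COLUMNS)
        for h in list(key_hits_raw) + list(reaction_hits_raw):
            writer.writerow([h.protein_id, h.target_id, repr(h.bit_score), repr(h.evalue)])


def scan_all_hits(
    proteins: list[ProteinRecord], catalog: PathwayCatalog, n_null: int = 1000
) -> tuple[list[SearchHit], list[SearchHit]]:
    """Ungated native hits for all key enzymes and reaction references."""
    key_set = ProfileSet(_key_profiles(catalog))
    key_set.calibrate(n_null=n_null)
    key_raw = [h for hits in key_set.scan(proteins, with_evalue=True).values() for h in hits]
    rxn_set = ProfileSet.from_sequences(_reaction_targets(catalog))
    rxn_raw = [h for hits in rxn_set.scan(proteins, with_evalue=False).values() for h in hits]
    return key_raw, rxn_raw


def import_hits(
    path,
    catalog: PathwayCatalog,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
    mag_id: str = "",
) -> MagDetections:
    """Apply the key-enzyme and reaction gates to externally computed hits.

    Expected columns: protein_id, target_id, bit_score, evalue.  target_id is
    either a key-enzyme name or a reaction reference accession.  Unknown
    targets are skipped with a warning; malformed rows raise with the line
    number.
    """
    import warnings

    enzyme_cutoffs = {
        enzyme.enzyme_name: enzyme.evalue_cutoff
        for pathway in catalog.pathways
        for enzyme in pathway.key_enzymes
    }
    reaction_accessions = set(_reaction_targets(catalog))

    enzyme_hits: dict[str, list[SearchHit]] = {name: [] for name in enzyme_cutoffs}
    accession_best: dict[str, SearchHit] = {}

    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 1 if lines and lines[0].startswith("protein_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise SearchError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
        protein_id, target_id = parts[0], parts[1]
        try:
            bit = float(parts[2])
            ev = float(parts[3])
        except ValueError as exc:
            raise SearchError(f"{path}: line {lineno}: non-numeric score ({exc})") from exc
        hit = SearchHit(protein_id=protein_id, target_id=target_id, bit_score=bit, evalue=ev)
        if target_id in enzyme_cutoffs:
            if ev < enzyme_cutoffs[target_id]:
                enzyme_hits[target_id].append(hit)
        elif target_id in reaction_accessions:
            if bit > bitscore_min and (
                target_id not in accession_best
                or bit > accession_best[target_id].bit_score
            ):
                accession_best[target_id] = hit
        else:
            warnings.warn(f"{path}: line {lineno}: unknown target_id {target_id!r}; skipped")

    flags: dict[str, bool] = {}
    support: dict[str, list[SearchHit]] = {}
    reactions: dict[str, set[str]] = {}
    evidence: dict[str, dict[str, SearchHit]] = {}
    for pathway in catalog.pathways:
        pid = pathway.pathway_id
        flags[pid] = any(
            all(enzyme_hits[name] for name in group) for group in pathway.key_logic
        )
        support[pid] = [
            h for group in pathway.key_logic for name in group for h in enzyme_hits[name]
        ]
        reactions[pid] = set()
        evidence[pid] = {}
        if not flags[pid]:
            continue
        for reaction in pathway.reactions:
            hits = [
                accession_best[acc]
                for acc, _ in reaction.reference_sequences
                if acc in accession_best
            ]
            if hits:
                reactions[pid].add(reaction.reaction_id)
                evidence[pid][reaction.reaction_id] = max(hits, key=lambda h: h.bit_score)
    return MagDetections(
        mag_id=mag_id,
        key_pass=flags,
        key_hits=support,
        reactions=reactions,
        reaction_hits=evidence,
    )


def random_null_protein(length: int, seed: int) -> ProteinRecord:
    """Convenience: a background-composition random protein (for null tests)."""
    rng = np.random.default_rng(seed)
    return ProteinRecord(protein_id=f"null_{seed}", mag_id="null", sequence=random_protein(length, rng))
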
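"""Profile construction, scoring, E-value gates, and the hit import bridge."""

import math

import numpy as np
import pytest

from cfpscan import (
    ProteinRecord,
    annotate_reactions,
    best_ungapped_score,
    build_profile,
    calibrate_profile,
    score_protein,
    screen_key_enzymes,
)
from cfpscan.search import (
    SearchError,
    detect_pathways,
    export_hits,
    import_hits,
    scan_all_hits,
)
from cfpscan.sequences import AA_ALPHABET, mutate_protein, random_protein
from cfpscan.synth import generate_reference_fixture


def _protein(seq, pid="p1"):
    return ProteinRecord(protein_id=pid, mag_id="m1", sequence=seq)


# ---------------------------------------------------------------------------
# Profile construction


def test_single_seed_profile_argmax_recovers_seed():
    prof = build_profile(["MKV"])
    assert prof.ncols == 3
    assert "".join(AA_ALPHABET[i] for i in prof.consensus) == "MKV"


def test_duplicate_seeds_are_idempotent():
    one = build_profile(["MKVLWAAL"])
    two = build_profile(["MKVLWAAL", "MKVLWAAL"])
    np.testing.assert_allclose(one.matrix, two.matrix)


def test_polymorphic_column_scores_both_observed_residues():
    prof = build_profile(["MKV", "MRV"])
    col = prof.matrix[1, : len(AA_ALPHABET)]
    top2 = set(np.argsort(col)[-2:])
    assert top2 == {AA_ALPHABET.index("K"), AA_ALPHABET.index("R")}


def test_profile_build_errors():
    with pytest.raises(SearchError):
        build_profile([])
    with pytest.raises(SearchError):
        build_profile([""])
    with pytest.raises(SearchError, match="length"):
        build_profile(["MKV", "MKVL"])


# ---------------------------------------------------------------------------
# Oracle equivalence: exhaustive all-offsets scoring


def _oracle_score(profile, sequence):
    """Independent brute-force maximum over every ungapped placement."""
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    n, L = profile.ncols, len(sequence)
    best = -math.inf
    if L >= n:
        offsets = range(L - n + 1)
        for j in offsets:
            s = 0.0
            for c in range(n):
                aa = sequence[j + c]
                s += profile.matrix[c, idx.get(aa, len(AA_ALPHABET))]
            best = max(best, s)
    else:
        for j in range(n - L + 1):
            s = 0.0
            for c in range(L):
                aa = sequence[c]
                s += profile.matrix[j + c, idx.get(aa, len(AA_ALPHABET))]
            best = max(best, s)
    return best


def test_bit_scores_match_exhaustive_oracle():
    rng = np.random.default_rng(2024)
    for trial in range(100):
        ncols = int(rng.integers(3, 21))
        plen = int(rng.integers(3, 51))
        n_seeds = int(rng.integers(1, 4))
        seeds = [random_protein(ncols, rng) for _ in range(n_seeds)]
        prof = build_profile(seeds)
        protein = random_protein(plen, rng)
        native, _ = best_ungapped_score(prof, protein)
        assert native == pytest.approx(_oracle_score(prof, protein), abs=1e-9)


# ---------------------------------------------------------------------------
# Scoring and E-values


def test_self_score_is_the_window_maximum():
    seed = random_protein(80, np.random.default_rng(5))
    prof = calibrate_profile(build_profile([seed], name="self"), n_null=300)
    hit = score_protein(prof, _protein(seed))
    self_score, offset = best_ungapped_score(prof, seed)
    assert hit.bit_score == pytest.approx(self_score)
    assert offset == 0
    assert hit.evalue < 1e-99
    assert hit.percent_identity == pytest.approx(100.0)


def test_uncalibrated_profile_refuses_to_score():
    prof = build_profile(["MKVLWAAL"])
    with pytest.raises(SearchError, match="calibrat"):
        score_protein(prof, _protein("MKVLWAAL"))


def test_random_proteins_usually_score_evalue_above_one():
    seed = random_protein(120, np.random.default_rng(11))
    prof = calibrate_profile(build_profile([seed], name="null-test"), n_null=500)
    rng = np.random.default_rng(99)
    above = sum(
        score_protein(prof, _protein(random_protein(220, rng))).evalue >= 1.0
        for _ in range(50)
    )
    assert above > 25  # clear majority


def test_mutated_seed_scores_between_null_and_self():
    rng = np.random.default_rng(7)
    seed = random_protein(150, rng)
    prof = calibrate_profile(build_profile([seed], name="mut"), n_null=300)
    self_score, _ = best_ungapped_score(prof, seed)
    mutated, _ = best_ungapped_score(prof, mutate_protein(seed, 0.9, rng))
    null_mean = float(
        np.mean([best_ungapped_score(prof, random_protein(150, rng))[0] for _ in range(20)])
    )
    assert null_mean < mutated < self_score


def test_evalue_decreases_with_bit_score():
    seed = random_protein(100, np.random.default_rng(3))
    prof = calibrate_profile(build_profile([seed], name="mono"), n_null=300)
    rng = np.random.default_rng(4)
    pairs = []
    for identity in (0.5, 0.7, 0.9, 1.0):
        hit = score_protein(prof, _protein(mutate_protein(seed, identity, rng)))
        pairs.append((hit.bit_score, hit.evalue))
    pairs.sort()
    evalues = [e for _, e in pairs]
    assert all(b >= a for a, b in zip(evalues[1:], evalues[:-1]))


# ---------------------------------------------------------------------------
# Key-enzyme screen


def test_implanted_hbd_flags_both_hydroxybutyrate_cycles(catalog):
    rng = np.random.default_rng(12)
    hbd_seed = catalog.pathway("HPHB").key_enzymes[0].seed_sequences[0]
    proteins = [_protein(mutate_protein(hbd_seed, 0.95, rng), "hbd_like")]
    flags, support = screen_key_enzymes(proteins, catalog)
    assert flags["HPHB"] and flags["DCHB"]
    assert not any(flags[p] for p in ("rTCA1", "rTCA2", "3HP", "CBB"))
    assert support["HPHB"] and support["DCHB"]


def test_ccl_without_ccs_fails_rtca2_all_of_logic(catalog):
    ccl_seed = next(
        k.seed_sequences[0]
        for k in catalog.pathway("rTCA2").key_enzymes
        if k.enzyme_name == "CCL"
    )
    flags, _ = screen_key_enzymes([_protein(ccl_seed, "ccl")], catalog)
    assert not flags["rTCA2"]


def test_empty_mag_passes_no_gate(catalog):
    flags, _ = screen_key_enzymes([], catalog)
    assert not any(flags.values())


def test_raising_evalue_cutoff_never_removes_detections(catalog, markers):
    mag = generate_reference_fixture("CBB", catalog, markers)
    strict, _ = screen_key_enzymes(mag.proteins, catalog, evalue_cutoff=1e-99)
    loose, _ = screen_key_enzymes(mag.proteins, catalog, evalue_cutoff=1e-20)
    assert {p for p, ok in strict.items() if ok} <= {p for p, ok in loose.items() if ok}


# ---------------------------------------------------------------------------
# Reaction annotation


def test_full_hphb_fixture_detects_all_16_reactions(catalog, markers):
    mag = generate_reference_fixture("HPHB", catalog, markers)
    detected, evidence = annotate_reactions(mag.proteins, catalog, pathway_ids=["HPHB"])
    assert detected["HPHB"] == set(catalog.pathway("HPHB").reaction_ids)
    assert len(evidence["HPHB"]) == 16


def test_raising_bitscore_floor_never_adds_detections(catalog, markers):
    rng = np.random.default_rng(8)
    proteins = [
        _protein(mutate_protein(seq, 0.7, rng), f"p{i}")
        for i, (_, seq) in enumerate(
            catalog.pathway("rTCA1").reaction("1.1.1.42").reference_sequences
        )
    ]
    low, _ = annotate_reactions(proteins, catalog, bitscore_min=50, pathway_ids=["rTCA1"])
    high, _ = annotate_reactions(proteins, catalog, bitscore_min=200, pathway_ids=["rTCA1"])
    assert high["rTCA1"] <= low["rTCA1"]


# ---------------------------------------------------------------------------
# Hit import / export bridge


def test_import_gates_match_native_detections(tmp_path, catalog, markers):
    mag = generate_reference_fixture("rTCA1", catalog, markers)
    native = detect_pathways(mag.proteins, catalog, mag_id=mag.mag_id)
    key_raw, rxn_raw = scan_all_hits(mag.proteins, catalog)
    path = tmp_path / "hits.tsv"
    export_hits(path, key_raw, rxn_raw)
    imported = import_hits(path, catalog, mag_id=mag.mag_id)
    assert imported.key_pass == native.key_pass
    assert imported.reactions == native.reactions


def test_import_evalue_gate(tmp_path, catalog):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "protein_id\ttarget_id\tbit_score\tevalue\n"
        "p1\tACLa\t500\t1e-120\n"
        "p2\tACLb\t500\t1e-120\n"
    )
    det = import_hits(path, catalog)
    assert det.key_pass["rTCA1"]

    path.write_text(
        "protein_id\ttarget_id\tbit_score\tevalue\n"
        "p1\tACLa\t500\t1e-50\n"
        "p2\tACLb\t500\t1e-50\n"
    )
    det = import_hits(path, catalog)
    assert not det.key_pass["rTCA1"]


def test_import_bitscore_boundary_is_strict(tmp_path, catalog):
    # A reaction hit at exactly the floor does not count.
    acc = catalog.pathway("HPHB").reaction("1.2.1.76").reference_sequences[0][0]
    path = tmp_path / "hits.tsv"
    path.write_text(
        "protein_id\ttarget_id\tbit_score\tevalue\n"
        f"p0\tHBD\t900\t1e-200\n"
        f"p1\t{acc}\t100\t1e-200\n"
        f"p2\t{acc}\t100.5\t1e-200\n"
    )
    det = import_hits(path, catalog)
    assert "1.2.1.76" in det.reactions["HPHB"]
    path.write_text(
        "protein_id\ttarget_id\tbit_score\tevalue\n"
        f"p0\tHBD\t900\t1e-200\n"
        f"p1\t{acc}\t100\t1e-200\n"
    )
    det = import_hits(path, catalog)
    assert "1.2.1.76" not in det.reactions["HPHB"]


def test_import_empty_and_malformed(tmp_path, catalog):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    det = import_hits(empty, catalog)
    assert not any(det.key_pass.values())
    assert all(not v for v in det.reactions.values())

    bad = tmp_path / "bad.tsv"
    bad.write_text("p1\tACLa\tnot_a_number\t1e-120\n")
    with pytest.raises(SearchError, match="line 1"):
        import_hits(bad, catalog)

    unknown = tmp_path / "unknown.tsv"
    unknown.write_text("p1\tno_such_target\t500\t1e-120\n")
    with pytest.warns(UserWarning, match="unknown target_id"):
        import_hits(unknown, catalog)
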
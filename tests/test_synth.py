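"""Generator determinism, truth consistency, and dose-response behavior."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from cfpscan import (
    call_pathways,
    detect_pathways,
    estimate_completeness,
    generate_cohort,
    generate_reference_fixture,
)
from cfpscan.synth import (
    ContaminationSpec,
    MagSpec,
    SyntheticCohortSpec,
    build_cohort,
    generate_mag,
)


def _dir_digest(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
    }


def _small_spec(seed=7):
    return SyntheticCohortSpec(
        seed=seed,
        mags=[
            MagSpec(
                mag_id="tp0",
                implanted_pathways={"CBB": 1.0},
                enzyme_identity_target=0.9,
                marker_retention=0.9,
                n_decoys=10,
            ),
            MagSpec(
                mag_id="tp1",
                implanted_pathways={"rTCA1": 1.0},
                enzyme_identity_target=0.85,
                n_decoys=10,
            ),
            MagSpec(
                mag_id="tp2",
                implanted_pathways={"HPHB": 1.0},
                n_decoys=5,
                domain_label="archaea",
            ),
            MagSpec(mag_id="neg0", n_decoys=15),
            MagSpec(
                mag_id="cont0",
                n_decoys=10,
                contamination=ContaminationSpec(insert_pathway_id="3HP"),
            ),
        ],
    )


def test_same_seed_reproduces_cohort_byte_for_byte(tmp_path, catalog, markers):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_cohort(_small_spec(), catalog, a, markers)
    generate_cohort(_small_spec(), catalog, b, markers)
    assert _dir_digest(a) == _dir_digest(b)


def test_different_seeds_differ(tmp_path, catalog, markers):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_cohort(_small_spec(seed=7), catalog, a, markers)
    generate_cohort(_small_spec(seed=8), catalog, b, markers)
    assert _dir_digest(a) != _dir_digest(b)


def test_truth_table_matches_spec(catalog, markers):
    cohort = build_cohort(_small_spec(), catalog, markers)
    truth = cohort.truth
    positives = [r.mag_id for r in truth.rows if r.true_pathways]
    assert sorted(positives) == ["cont0", "tp0", "tp1", "tp2"]
    assert truth.row("tp0").true_pathways == ("CBB",)
    assert truth.row("neg0").true_pathways == ()
    assert truth.row("cont0").contaminated
    assert truth.row("cont0").contaminant_pathway == "3HP"
    # Retained reactions are consistent with the emitted proteome size.
    assert len(truth.row("tp1").retained_reactions["rTCA1"]) == 9


def test_generated_files_round_trip_through_reader(tmp_path, catalog, markers):
    from cfpscan import read_mag

    out = tmp_path / "cohort"
    cohort = generate_cohort(_small_spec(), catalog, out, markers)
    mag = read_mag(
        out / "tp0.faa",
        mag_id="tp0",
        nucleotide_fasta=out / "tp0.fna",
        gff=out / "tp0.gff",
    )
    original = cohort.mags[0]
    assert {p.protein_id for p in mag.proteins} == {
        p.protein_id for p in original.proteins
    }
    reread = {p.protein_id: (p.contig_id, p.start, p.end) for p in mag.proteins}
    for p in original.proteins:
        assert reread[p.protein_id] == (p.contig_id, p.start, p.end)


def test_dose_response_is_monotone(catalog, markers):
    """Sweeping reaction retention downward never increases observed
    completeness."""
    from cfpscan.caller import observed_completeness

    pathway = catalog.pathway("HPHB")
    previous = 101.0
    for retention in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
        spec = MagSpec(
            mag_id=f"d{int(retention * 100)}",
            implanted_pathways={"HPHB": retention},
            n_decoys=5,
        )
        gen = generate_mag(spec, catalog, markers, np.random.default_rng([3, 1]))
        det = detect_pathways(gen.record.proteins, catalog, annotate_all=True)
        obs = observed_completeness(det.reactions["HPHB"], pathway)
        assert obs <= previous
        previous = obs


def test_near_miss_generator_drops_noncarboxylation_first(catalog, markers):
    spec = MagSpec(
        mag_id="nm", implanted_pathways={"HPHB": 14 / 16}, n_decoys=0
    )
    gen = generate_mag(spec, catalog, markers, np.random.default_rng(5))
    retained = set(gen.truth.retained_reactions["HPHB"])
    assert set(catalog.pathway("HPHB").carboxylation_ids) <= retained
    assert len(retained) == 14


def test_reference_fixture_scores_complete(catalog, markers):
    mag = generate_reference_fixture("rTCA1", catalog, markers)
    comp, cont = estimate_completeness(mag, markers)
    assert comp == 100.0 and cont == 0.0
    det = detect_pathways(mag.proteins, catalog, mag_id=mag.mag_id)
    call = {c.pathway_id: c for c in call_pathways(mag, catalog, det)}["rTCA1"]
    assert call.present
    assert call.observed_completeness_pct == 100.0
    assert call.adjusted_completeness_pct == 100.0


def test_hphb_fixture_passes_both_hbd_gates_but_only_hphb_presents(catalog, markers):
    mag = generate_reference_fixture("HPHB", catalog, markers)
    estimate_completeness(mag, markers)
    det = detect_pathways(mag.proteins, catalog, mag_id=mag.mag_id)
    assert det.key_pass["HPHB"] and det.key_pass["DCHB"]
    calls = {c.pathway_id: c for c in call_pathways(mag, catalog, det)}
    assert calls["HPHB"].present
    assert not calls["DCHB"].present
    # Overlap between the cycles is the shared succinyl-CoA -> acetyl-CoA arm.
    shared = set(catalog.pathway("HPHB").reaction_ids) & set(
        catalog.pathway("DCHB").reaction_ids
    )
    assert det.reactions["DCHB"] == shared


def test_domain_label_selects_marker_family(catalog, markers):
    spec = MagSpec(mag_id="arc", domain_label="archaea", n_decoys=0)
    gen = generate_mag(spec, catalog, markers, np.random.default_rng(9))
    comp, _ = estimate_completeness(gen.record, markers["archaea"])
    assert comp == 100.0
    assert len(gen.record.proteins) == markers["archaea"].n_markers


def test_invalid_spec_values_rejected():
    with pytest.raises(ValueError, match="retention"):
        MagSpec(mag_id="x", implanted_pathways={"CBB": 1.5})
    with pytest.raises(ValueError, match="identity"):
        MagSpec(mag_id="x", enzyme_identity_target=-0.1)


def test_forced_missing_must_name_real_reactions(catalog, markers):
    spec = MagSpec(
        mag_id="x",
        implanted_pathways={"HPHB": 1.0},
        forced_missing={"HPHB": ("9.9.9.9",)},
    )
    with pytest.raises(ValueError, match="forced_missing"):
        generate_mag(spec, catalog, markers, np.random.default_rng(1))
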
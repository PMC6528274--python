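"""Synthetic pair generator: determinism, truth replay, rate calibration."""

from __future__ import annotations

import numpy as np
import pytest

from memalign import (
    PRESETS,
    MutationProfile,
    apply_edits,
    generate_dataset,
    generate_pair,
    generate_pairs,
)


def test_no_mutation_identity():
    rng = np.random.default_rng(61)
    rec = generate_pair(MutationProfile(80, 0.0, 0.0, 0.0), rng)
    assert rec.query == rec.target and rec.edits == ()


def test_all_snp():
    rng = np.random.default_rng(62)
    rec = generate_pair(MutationProfile(60, 1.0, 0.0, 0.0), rng)
    assert len(rec.query) == 60
    assert sum(a != b for a, b in zip(rec.target, rec.query)) == 60


def test_truth_replay():
    rng = np.random.default_rng(63)
    for profile in (
        MutationProfile(50, 0.1, 0.05, 0.3),
        MutationProfile(200, 0.02, 0.01, 0.1),
        PRESETS["DSH"],
    ):
        for _ in range(200):
            rec = generate_pair(profile, rng)
            assert apply_edits(rec.target, rec.edits) == rec.query


def test_determinism(tmp_path):
    a = generate_dataset(PRESETS["DSL"], 30, tmp_path / "a", seed=9)
    b = generate_dataset(PRESETS["DSL"], 30, tmp_path / "b", seed=9)
    c = generate_dataset(PRESETS["DSL"], 30, tmp_path / "c", seed=10)
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes()
    assert a["tsv"].read_bytes() != c["tsv"].read_bytes()


def test_dataset_counts(tmp_path):
    paths = generate_dataset(PRESETS["DSL"], 50, tmp_path, seed=1)
    targets = paths["targets"].read_text().count(">")
    queries = paths["queries"].read_text().count(">")
    rows = len(paths["tsv"].read_text().strip().splitlines()) - 1  # header
    assert targets == queries == rows == 50


def test_dataset_truth_replays(tmp_path):
    paths = generate_dataset(MutationProfile(60, 0.05, 0.02, 0.2), 40, tmp_path, seed=3)
    pairs = {}
    for line in paths["tsv"].read_text().splitlines()[1:]:
        t, q = line.split("\t")
        pairs[f"pair{len(pairs)}"] = (t, q)
    from memalign import Edit

    edits: dict[str, list[Edit]] = {pid: [] for pid in pairs}
    for line in paths["truth"].read_text().splitlines()[1:]:
        pid, pos, op, length, bases = (line.split("\t") + [""])[:5]
        edits[pid].append(Edit(int(pos), op, int(length), bases))
    for pid, (t, q) in pairs.items():
        assert apply_edits(t, edits[pid]) == q


def test_snp_rate_calibration():
    """Empirical SNP count per pair stays within 3 standard errors of the
    nominal length * rate for the low-divergence short preset."""
    profile = PRESETS["DSL"]
    recs = generate_pairs(profile, 10_000, 77)
    counts = [sum(1 for e in r.edits if e.op == "snp") for r in recs]
    mean = np.mean(counts)
    nominal = profile.length * profile.snp_rate  # 1.25
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - nominal) < 3 * se


def test_indel_rate_calibration():
    profile = MutationProfile(200, 0.0, 0.01, 0.3)
    recs = generate_pairs(profile, 5_000, 78)
    counts = [len(r.edits) for r in recs]
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    # deletions consume unexamined bases, a sub-1% downward bias at 3-sigma scale
    assert abs(mean - 200 * 0.01) < 3 * se


def test_preset_values():
    assert PRESETS["DSL"] == MutationProfile(125, 0.01, 0.001, 0.05, "DSL")
    assert PRESETS["DLL"].length == 500
    assert PRESETS["DSH"].snp_rate == 0.05
    assert PRESETS["DLH"].indel_expansion == 0.10


def test_invalid_profile():
    with pytest.raises(ValueError):
        MutationProfile(0)
    with pytest.raises(ValueError):
        MutationProfile(10, snp_rate=1.5)


def test_supplied_target_used():
    rng = np.random.default_rng(64)
    rec = generate_pair(MutationProfile(10, 0.0, 0.0, 0.0), rng, target="ACGTACGTAA")
    assert rec.target == "ACGTACGTAA" and rec.query == rec.target
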
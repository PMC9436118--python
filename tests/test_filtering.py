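import numpy as np
import pytest

from speach_af.filtering import (
    ScoreTable,
    clash_pairs,
    clash_proxy_score,
    ensemble_pca,
    filter_sets,
    prune_outliers,
    relative_mp,
)
from speach_af.fixtures import (
    HingeToySpec,
    hinge_model,
    make_hinge_ensemble,
    make_score_table,
)
from speach_af.metrics import ModelEnsemble
from speach_af.structures import Residue, StructureModel


# -------------------------------------------------------------- filter_sets


def test_filter_sets_worked_example():
    table = ScoreTable.from_rows(
        [("a1", "A", 1.6), ("a2", "A", 1.7), ("a3", "A", 1.8),
         ("b1", "B", 2.8), ("b2", "B", 2.9), ("b3", "B", 3.0),
         ("c1", "C", 1.7), ("c2", "C", 1.7), ("c3", "C", 1.7)]
    )
    kept, discarded, stats = filter_sets(table)
    assert stats.median == pytest.approx(1.7)
    assert stats.scale == pytest.approx(0.604, abs=0.005)
    assert discarded == ["B"]
    assert kept == ["A", "C"]


def test_filter_sets_identical_scores_all_kept():
    table = ScoreTable.from_rows(
        [(f"{s}{i}", s, 2.0) for s in "ABC" for i in range(3)]
    )
    kept, discarded, stats = filter_sets(table)
    assert stats.scale == 0.0
    assert discarded == []
    assert set(kept) == {"A", "B", "C"}


def test_filter_sets_single_set_kept_with_warning():
    table = ScoreTable.from_rows([("m1", "only", 1.0), ("m2", "only", 9.0)])
    with pytest.warns(UserWarning, match="one set"):
        kept, discarded, _ = filter_sets(table)
    assert kept == ["only"] and discarded == []


def test_filter_sets_invariant_to_row_order_and_labels():
    rng = np.random.default_rng(0)
    rows = [(f"m{i}", f"s{i % 5}", float(rng.normal(1.7, 0.2))) for i in range(60)]
    kept1, disc1, _ = filter_sets(ScoreTable.from_rows(rows))
    shuffled = [rows[i] for i in rng.permutation(len(rows))]
    relabeled = [(f"x{i}", s, v) for i, (_, s, v) in enumerate(shuffled)]
    kept2, disc2, _ = filter_sets(ScoreTable.from_rows(relabeled))
    assert set(kept1) == set(kept2) and set(disc1) == set(disc2)


@pytest.mark.parametrize("seed", range(100))
def test_filter_sets_equals_arithmetic_oracle(seed):
    rng = np.random.default_rng(seed)
    n_sets = int(rng.integers(2, 12))
    rows = []
    for s in range(n_sets):
        n_models = int(rng.integers(1, 16))
        mean = float(rng.uniform(1.4, 2.6))
        for m in range(n_models):
            rows.append((f"s{s}_m{m}", f"s{s}", float(rng.normal(mean, 0.1))))
    kept, discarded, _ = filter_sets(ScoreTable.from_rows(rows))
    # independent arithmetic oracle with plain python
    scores = sorted(v for _, _, v in rows)
    n = len(scores)
    median = scores[n // 2] if n % 2 else 0.5 * (scores[n // 2 - 1] + scores[n // 2])
    mu = sum(scores) / n
    sd = (sum((v - mu) ** 2 for v in scores) / (n - 1)) ** 0.5
    expected_discard = set()
    for s in range(n_sets):
        vals = [v for _, sid, v in rows if sid == f"s{s}"]
        if sum(vals) / len(vals) > median + sd:
            expected_discard.add(f"s{s}")
    assert set(discarded) == expected_discard
    assert set(kept) == {f"s{s}" for s in range(n_sets)} - expected_discard


def test_planted_high_score_sets_recalled():
    sets = [f"set{i:02d}" for i in range(22)]
    planted = ["set03", "set19"]
    table = make_score_table(sets, base_sd=0.08, outlier_sets=planted,
                             outlier_shift=0.6, seed=9)
    pooled_sd = float(np.std(table.df["score"], ddof=1))
    assert 0.6 >= 3 * pooled_sd  # planted shift is >= 3 pooled SDs
    _, discarded, _ = filter_sets(table)
    assert set(planted) <= set(discarded)  # recall 1.0


def test_relative_mp():
    assert relative_mp(1.6, 1.6) == 0.0
    assert relative_mp(2.0, 1.6) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        relative_mp(2.0, 0.0)
    scores = np.array([1.6, 1.8, 2.4])
    vec = [relative_mp(s, scores.min()) for s in scores]
    np.testing.assert_allclose(vec, (scores - 1.6) / 1.6)


def test_score_table_csv_roundtrip(tmp_path):
    table = make_score_table(["a", "b"], seed=1)
    p = tmp_path / "scores.csv"
    table.to_csv(p)
    back = ScoreTable.from_csv(p)
    assert back.df.shape == table.df.shape
    np.testing.assert_allclose(back.df["score"], table.df["score"])


# -------------------------------------------------------------- clash proxy


def test_clash_proxy_zero_on_extended_and_closed_toy():
    spec = HingeToySpec(noise_sd=0.0)
    assert clash_proxy_score(hinge_model(spec, 30.0)) == 0.0
    # an isolated extended strand
    strand = StructureModel(
        model_id="ext",
        residues=[Residue(i, "GLY", [("N", i * 3.8 - 1.45, 0, 0),
                                      ("CA", i * 3.8, 0, 0),
                                      ("C", i * 3.8 + 1.0, 0, 0),
                                      ("O", i * 3.8 + 1.0, 1.23, 0)])
                  for i in range(1, 21)],
    )
    assert clash_proxy_score(strand) == 0.0


def test_single_planted_overlap_counted_once():
    residues = [
        Residue(1, "GLY", [("CA", 0.0, 0.0, 0.0)]),
        Residue(2, "GLY", [("CA", 3.8, 0.0, 0.0)]),
        Residue(3, "GLY", [("CA", 1.0, 0.0, 0.0)]),  # 1.0 Å from residue 1
    ]
    model = StructureModel(model_id="m", residues=residues)
    pairs = clash_pairs(model)
    assert len(pairs) == 1
    assert pairs[0][:4] == (1, "CA", 3, "CA")
    assert clash_proxy_score(model) == pytest.approx(1000.0 / 3)


@pytest.mark.parametrize("seed", range(10))
def test_clash_count_equals_brute_force(seed):
    from speach_af.structures import infer_element
    from speach_af.filtering import _VDW, _VDW_DEFAULT

    rng = np.random.default_rng(seed)
    model = hinge_model(HingeToySpec(noise_sd=1.0), float(rng.uniform(2, 50)),
                        noise_rng=rng)
    atoms = []
    for i, res in enumerate(model.residues, start=1):
        for name, x, y, z in res.atoms:
            atoms.append((i, name, np.array([x, y, z]),
                          _VDW.get(infer_element(name), _VDW_DEFAULT)))
    expected = 0
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            if abs(atoms[a][0] - atoms[b][0]) <= 1:
                continue
            d = np.linalg.norm(atoms[a][2] - atoms[b][2])
            if d < atoms[a][3] + atoms[b][3] - 0.4:
                expected += 1
    assert len(clash_pairs(model)) == expected


# --------------------------------------------------------------------- PCA


def _toy_pca_ensemble(n=20, seed=0, modes=1, noise=0.3):
    spec = HingeToySpec(noise_sd=noise, modes=modes)
    models = make_hinge_ensemble(spec, n, seed=seed)
    ens = ModelEnsemble(models=models,
                        set_of={m.model_id: "s0" for m in models})
    return spec, ens


def test_pca_invariants_and_trace_conservation():
    _, ens = _toy_pca_ensemble(15, seed=2)
    pca = ensemble_pca(ens)
    pca.validate()
    assert np.all(pca.eigenvalues >= -1e-12)
    assert pca.eigenvalues.sum() == pytest.approx(pca.total_variance, rel=1e-9)


def test_pca_two_conformations_rank_one(toy_spec):
    spec = HingeToySpec(noise_sd=0.0)
    a = hinge_model(spec, 10.0, model_id="a")
    b = hinge_model(spec, 40.0, model_id="b")
    # duplicated endpoints: exactly one direction of variation
    models = [a, b, hinge_model(spec, 10.0, model_id="a2"),
              hinge_model(spec, 40.0, model_id="b2")]
    ens = ModelEnsemble(models=models, set_of={m.model_id: "s" for m in models})
    pca = ensemble_pca(ens)
    assert pca.eigenvalues[0] > 1.0
    assert pca.eigenvalues[1] < 1e-8 * pca.eigenvalues[0]


def test_pca_projection_invariant_to_model_order():
    _, ens = _toy_pca_ensemble(12, seed=4)
    pca1 = ensemble_pca(ens)
    rng = np.random.default_rng(0)
    order = rng.permutation(len(ens.models))
    ens2 = ModelEnsemble(models=[ens.models[i] for i in order],
                         set_of=dict(ens.set_of))
    pca2 = ensemble_pca(ens2)
    for mid in pca1.projections:
        # iterative-mean convergence tolerance bounds the order dependence
        np.testing.assert_allclose(
            pca1.projections[mid][:2], pca2.projections[mid][:2], atol=1e-3
        )


def test_pca_matches_sklearn_on_aligned_deviations():
    from sklearn.decomposition import PCA as SkPCA

    _, ens = _toy_pca_ensemble(18, seed=6)
    pca = ensemble_pca(ens)
    X = np.stack([pca._coords[m.model_id].ravel() for m in ens.models])
    sk = SkPCA(n_components=3).fit(X)
    # sklearn centers at the column mean; the iterative mean converges to it,
    # so leading eigenvalues agree up to the n/(n-1) variance convention
    n = len(ens.models)
    np.testing.assert_allclose(
        pca.eigenvalues[:3], sk.explained_variance_[:3] * (n - 1) / n, rtol=1e-3
    )


def test_pca_references_projected_not_fitted(toy_spec):
    spec = HingeToySpec(noise_sd=0.1)
    _, ens = _toy_pca_ensemble(15, seed=8, noise=0.1)
    ref = hinge_model(spec, 30.0, model_id="xtal")
    pca = ensemble_pca(ens, references=[ref])
    assert "xtal" in pca.ref_projections
    assert "xtal" not in pca.projections
    # fit is unchanged by adding a projected-only reference
    pca_plain = ensemble_pca(ens)
    np.testing.assert_allclose(pca.eigenvalues, pca_plain.eigenvalues, atol=1e-9)


def test_pca_needs_three_conformations(toy_spec):
    models = make_hinge_ensemble(HingeToySpec(), 2, seed=0)
    ens = ModelEnsemble(models=models, set_of={m.model_id: "s" for m in models})
    with pytest.raises(ValueError):
        ensemble_pca(ens)


# ----------------------------------------------------------- prune_outliers


def _planted_outlier_pca(n_core=40, n_out=5, seed=1):
    spec = HingeToySpec(angle_range=(20.0, 28.0), noise_sd=0.2)
    core = make_hinge_ensemble(spec, n_core, seed=seed, id_prefix="core")
    # far outliers: wildly open conformations, 10x the core spread
    out_spec = HingeToySpec(angle_range=(20.0, 28.0), noise_sd=0.2)
    outliers = [
        hinge_model(out_spec, 140.0 + 3 * i, noise_rng=np.random.default_rng(seed + i),
                    model_id=f"out{i}")
        for i in range(n_out)
    ]
    models = core + outliers
    ens = ModelEnsemble(models=models, set_of={m.model_id: "s" for m in models})
    return ensemble_pca(ens)


def test_prune_no_outliers_in_tight_cluster():
    spec = HingeToySpec(angle_range=(24.0, 26.0), noise_sd=0.2)
    models = make_hinge_ensemble(spec, 30, seed=3)
    ens = ModelEnsemble(models=models, set_of={m.model_id: "s" for m in models})
    kept, removed, _ = prune_outliers(ensemble_pca(ens), k=6.0)
    assert removed == []
    assert len(kept) == 30


def test_prune_removes_exactly_planted_outliers():
    pca = _planted_outlier_pca()
    kept, removed, refit = prune_outliers(pca, k=3.5)
    assert sorted(removed) == [f"out{i}" for i in range(5)]
    assert len(kept) == 40
    refit.validate()


def test_prune_is_fixed_point_and_monotone_in_k():
    pca = _planted_outlier_pca()
    kept, removed, refit = prune_outliers(pca, k=3.5)
    _, removed2, _ = prune_outliers(refit, k=3.5)
    assert removed2 == []
    # larger k never removes more
    _, removed_lo, _ = prune_outliers(pca, k=2.5)
    _, removed_hi, _ = prune_outliers(pca, k=8.0)
    assert len(removed_hi) <= len(removed) <= len(removed_lo)


def test_prune_honors_manual_exclusions_and_errors():
    pca = _planted_outlier_pca()
    kept, removed, _ = prune_outliers(pca, k=3.5, manual_exclude=["core_000"])
    assert "core_000" in removed and "core_000" not in kept
    small_spec = HingeToySpec(noise_sd=0.1)
    models = make_hinge_ensemble(small_spec, 3, seed=0)
    ens = ModelEnsemble(models=models, set_of={m.model_id: "s" for m in models})
    with pytest.raises(ValueError):
        prune_outliers(ensemble_pca(ens))
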
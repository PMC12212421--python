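"""MIL transformer: gradients, structural invariants, training protocol."""

import math

import numpy as np
import pytest

from hnmil import mil as milmod
from hnmil import stats as st
from hnmil.features import InstanceBag
from tests.conftest import MIL_RECOVERY_CONFIG

SMALL = dict(embed_dim_in=5, model_dim=8, n_heads=2, n_layers=2, epochs=2,
             patience=2, seed=3)


def _bag(E, pid="p"):
    return InstanceBag(patient_id=pid, embeddings=E, embeddings_aug=E.copy())


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def test_inverse_proportion_weights():
    probs = [0.8, 0.3]
    labels = [1, 0]
    props = {1: 0.25, 0: 0.75}
    expected = np.mean([-4.0 * math.log(0.8), -(4 / 3) * math.log(0.7)])
    assert milmod.weighted_bce(probs, labels, props) == pytest.approx(expected)


def test_bce_limits_and_balanced_equivalence():
    assert milmod.weighted_bce([1 - 1e-12, 1e-12], [1, 0], {0: 0.5, 1: 0.5}) < 1e-9
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.95, 10)
    y = np.array([0, 1] * 5)
    unweighted = np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p)))
    assert milmod.weighted_bce(p, y, {0: 0.5, 1: 0.5}) == pytest.approx(2 * unweighted)
    with pytest.raises(ValueError):
        milmod.weighted_bce(p, y, {0: 1.0, 1: 0.0})


# ---------------------------------------------------------------------------
# gradients and forward invariants
# ---------------------------------------------------------------------------


def test_backward_matches_finite_differences():
    cfg = milmod.MILConfig(**SMALL)
    net = milmod.MILTransformer(cfg, rng=np.random.default_rng(0))
    rng = np.random.default_rng(1)
    X = rng.standard_normal((4, 5))
    y, w = 1.0, 2.0

    def loss():
        p = min(max(net.forward(X)["score"], 1e-12), 1 - 1e-12)
        return -w * (y * math.log(p) + (1 - y) * math.log(1 - p))

    cache = net.forward(X)
    grads = net.backward(cache, w * (cache["score"] - y))
    eps = 1e-6
    for key, v in net.params.items():
        for _ in range(min(v.size, 4)):
            idx = tuple(rng.integers(0, s) for s in v.shape) if v.ndim else ()
            orig = v[idx]
            v[idx] = orig + eps
            lp = loss()
            v[idx] = orig - eps
            lm = loss()
            v[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key][idx]
            assert abs(num - ana) < 1e-4 * max(1.0, abs(num) + abs(ana)), key


def test_attention_normalization_and_range():
    cfg = milmod.MILConfig(**SMALL)
    net = milmod.MILTransformer(cfg, rng=np.random.default_rng(2))
    for n in (1, 3, 17):
        X = np.random.default_rng(n).standard_normal((n, 5))
        pred = milmod.mil_forward(_bag(X), net)
        assert pred.attention.sum() == pytest.approx(1.0, abs=1e-6)
        assert (pred.attention >= 0).all()
        assert 0.0 <= pred.score <= 1.0


def test_identical_instances_get_uniform_attention():
    cfg = milmod.MILConfig(**SMALL)
    net = milmod.MILTransformer(cfg, rng=np.random.default_rng(2))
    X = np.tile(np.random.default_rng(5).standard_normal((1, 5)), (6, 1))
    pred = milmod.mil_forward(_bag(X), net)
    np.testing.assert_allclose(pred.attention, 1 / 6, atol=1e-12)


def test_score_invariant_to_instance_permutation():
    cfg = milmod.MILConfig(**SMALL)
    net = milmod.MILTransformer(cfg, rng=np.random.default_rng(2))
    X = np.random.default_rng(6).standard_normal((9, 5))
    perm = np.random.default_rng(7).permutation(9)
    a = milmod.mil_forward(_bag(X), net)
    b = milmod.mil_forward(_bag(X[perm]), net)
    assert b.score == pytest.approx(a.score, abs=1e-10)
    np.testing.assert_allclose(b.attention, a.attention[perm], atol=1e-10)


def test_forward_rejects_empty_and_mismatched_bags():
    cfg = milmod.MILConfig(**SMALL)
    net = milmod.MILTransformer(cfg)
    with pytest.raises(ValueError):
        net.forward(np.empty((0, 5)))
    with pytest.raises(ValueError, match="embed_dim_in"):
        net.forward(np.zeros((3, 7)))


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------


def _toy_training_set(n=24, d=6, seed=0):
    rng = np.random.default_rng(seed)
    bags, ys = [], []
    for i in range(n):
        y = i % 2
        E = rng.normal(2.0 * y - 1.0, 1.0, (rng.integers(3, 7), d))
        bags.append(_bag(E, f"p{i}"))
        ys.append(y)
    return bags, np.array(ys)


def test_stratified_folds_within_one_sample():
    labels = np.array([1] * 20 + [0] * 45)
    folds = milmod.stratified_folds(labels, n_folds=5, seed=1337)
    overall = labels.mean()
    for _, ho in folds:
        n_pos = labels[ho].sum()
        assert abs(n_pos - overall * len(ho)) <= 1


def test_training_is_deterministic_under_seed():
    bags, ys = _toy_training_set()
    cfg = milmod.MILConfig(embed_dim_in=6, model_dim=8, n_heads=2, n_layers=1,
                           epochs=3, patience=3, n_folds=2, seed=11, batch_size=4)
    f1 = milmod.stratified_folds(ys, cfg.n_folds, cfg.seed)
    f2 = milmod.stratified_folds(ys, cfg.n_folds, cfg.seed)
    for (a, b), (c, d) in zip(f1, f2):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)
    n1 = milmod.MILTransformer(cfg)
    n2 = milmod.MILTransformer(cfg)
    for k in n1.params:
        np.testing.assert_array_equal(n1.params[k], n2.params[k])
    m1 = milmod.train_mil_cv(bags, ys, cfg)
    m2 = milmod.train_mil_cv(bags, ys, cfg)
    for a, b in zip(m1, m2):
        assert a.holdout_auroc == b.holdout_auroc
        for k in a.model.params:
            np.testing.assert_array_equal(a.model.params[k], b.model.params[k])


def test_training_requires_two_patients_per_class():
    bags, _ = _toy_training_set(6)
    cfg = milmod.MILConfig(embed_dim_in=6, n_folds=2, epochs=1, patience=1)
    with pytest.raises(ValueError):
        milmod.train_mil_cv(bags, np.array([1, 0, 0, 0, 0, 0]), cfg)


def test_early_stopping_halts_when_holdout_loss_is_flat():
    bags, ys = _toy_training_set()
    cfg = milmod.MILConfig(embed_dim_in=6, model_dim=8, n_heads=2, n_layers=1,
                           epochs=40, patience=4, n_folds=2, seed=11,
                           batch_size=4, lr_initial=0.0)
    models = milmod.train_mil_cv(bags, ys, cfg)
    for m in models:  # zero learning rate: no improvement past epoch 0
        assert len(m.training_log) == cfg.patience + 1


def test_cosine_schedule_anneals_from_peak_to_zero():
    cfg = milmod.MILConfig(embed_dim_in=4, epochs=10, patience=10)
    lrs = [milmod.cosine_lr(e, cfg) for e in range(10)]
    assert lrs[0] == pytest.approx(cfg.lr_initial)
    assert lrs[-1] == pytest.approx(0.0, abs=1e-12)
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


@pytest.mark.parametrize(
    "aurocs,expected_fold",
    [
        ([0.60, 0.65, 0.70, 0.75, 0.80], 2),
        ([0.5, 0.5, 0.5, 0.5, 0.5], 0),
        ([0.6, 0.7, 0.7, 0.8], 1),
    ],
)
def test_median_auroc_model_selection(aurocs, expected_fold):
    models = [
        milmod.TrainedMILModel(model=None, config=None, fold_id=i, holdout_auroc=a)
        for i, a in enumerate(aurocs)
    ]
    assert milmod.select_deployment_model(models).fold_id == expected_fold


def test_predictions_independent_of_cohort_ordering():
    bags, ys = _toy_training_set(12)
    cfg = milmod.MILConfig(embed_dim_in=6, model_dim=8, n_heads=2, n_layers=1,
                           epochs=2, patience=2, n_folds=2, seed=5, batch_size=4)
    dep = milmod.select_deployment_model(milmod.train_mil_cv(bags, ys, cfg))
    fwd = milmod.predict_cohort(bags, dep)
    rev = milmod.predict_cohort(bags[::-1], dep)
    for a, b in zip(fwd, rev[::-1]):
        assert a.score == b.score
        assert 0.0 <= a.score <= 1.0


def test_attention_concentrates_on_signal_instances():
    """Positive bags contain shifted instances among pure noise; attention
    learned by the model should weight the signal instances higher."""
    rng = np.random.default_rng(0)
    d = 16
    bags, kinds, ys = [], [], []
    for i in range(80):
        y = i % 2
        n_sig = 3 if y else 0
        sig = rng.normal(3.0, 1.0, (n_sig, d))
        noise = rng.normal(0.0, 1.0, (8 - n_sig, d))
        E = np.vstack([sig, noise]) if n_sig else noise
        perm = rng.permutation(8)
        bags.append(_bag(E[perm], f"p{i}"))
        kinds.append(np.array([1] * n_sig + [0] * (8 - n_sig))[perm])
        ys.append(y)
    cfg = milmod.MILConfig(embed_dim_in=d, model_dim=16, n_heads=2, n_layers=1,
                           epochs=30, patience=30, n_folds=2, seed=42, batch_size=8)
    dep = milmod.select_deployment_model(milmod.train_mil_cv(bags, np.array(ys), cfg))
    sig_att, noise_att = [], []
    for b, k, y in zip(bags, kinds, ys):
        if y:
            att = milmod.mil_forward(b, dep).attention
            sig_att.append(att[k == 1].mean())
            noise_att.append(att[k == 0].mean())
    assert np.mean(sig_att) > np.mean(noise_att)


def test_deployed_model_recovers_imaging_risk_signal(os_split, mil_deployment):
    """Texture/size-driven risk: deployed 2D MIL beats chance on held-out
    patients while a label-permuted control stays near chance."""
    test_auroc = st.auroc(mil_deployment["test_scores"], os_split["y_test"])
    perm_auroc = st.auroc(mil_deployment["perm_scores"], os_split["y_test"])
    assert test_auroc > 0.70
    assert 0.4 <= perm_auroc <= 0.6
    mean_holdout = np.mean([m.holdout_auroc for m in mil_deployment["fold_models"]])
    assert mean_holdout > 0.70


def test_mil_config_validation():
    with pytest.raises(ValueError):
        milmod.MILConfig(embed_dim_in=4, patience=20, epochs=10)
    with pytest.raises(ValueError):
        milmod.MILConfig(embed_dim_in=4, n_folds=1)
    with pytest.raises(ValueError):
        milmod.MILConfig(embed_dim_in=4, model_dim=10, n_heads=4)


def test_recovery_config_matches_study_conditions():
    cfg = milmod.MILConfig(**MIL_RECOVERY_CONFIG)
    assert cfg.epochs <= 10 and cfg.embed_dim_in == 128
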
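"""Moderated linear-model engine: OLS, prior estimation, t/F, BH, validation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import bh_reference, ols_reference, quadratic_form_reference
from conftest import matrix_from
from glycophos.containers import make_design
from glycophos.modstats import (DesignSpec, SignifConfig, bh_adjust,
                                build_factorial_design, build_two_group_design,
                                estimate_prior, factorial_F, fit_models,
                                mark_significant, moderate, moderated_F,
                                moderated_t, one_tailed_validation, pairwise_de,
                                trigamma_inverse)

TWO_GROUP = DesignSpec(
    X=pd.DataFrame({"intercept": 1.0, "group": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]},
                   index=[f"s{j}" for j in range(6)]),
    contrasts={"diff": np.array([0.0, 1.0])},
)


def _fit(values, spec=TWO_GROUP):
    m = matrix_from(values, sample_ids=list(spec.X.index))
    return fit_models(m, spec)


# ----------------------------------------------------------------------
# OLS layer
# ----------------------------------------------------------------------

def test_exact_two_group_fit():
    spec = DesignSpec(X=pd.DataFrame({"intercept": 1.0, "group": [0.0, 0.0, 1.0, 1.0]},
                                     index=["a", "b", "c", "d"]),
                      contrasts={"diff": np.array([0.0, 1.0])})
    fit = _fit([[1.0, 1.0, 3.0, 3.0]], spec)
    assert fit.coef.iloc[0].tolist() == pytest.approx([1.0, 2.0])
    assert fit.sigma2.iloc[0] == pytest.approx(0.0, abs=1e-24)


def test_intercept_only_gives_feature_mean():
    spec = DesignSpec(X=pd.DataFrame({"intercept": [1.0] * 4},
                                     index=["a", "b", "c", "d"]))
    fit = _fit([[1.0, 2.0, 3.0, 6.0]], spec)
    assert fit.coef.iloc[0, 0] == pytest.approx(3.0)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(6), rng.normal(size=6), rng.normal(size=6)])
    spec = DesignSpec(X=pd.DataFrame(X, columns=["i", "a", "b"],
                                     index=[f"s{j}" for j in range(6)]))
    Y = rng.normal(size=(40, 6))
    fit = _fit(Y, spec)
    for g in range(40):
        beta, s2 = ols_reference(X, Y[g])
        assert np.allclose(fit.coef.iloc[g].to_numpy(), beta, atol=1e-10)
        assert fit.sigma2.iloc[g] == pytest.approx(s2, abs=1e-10)


def test_rank_deficient_design_rejected():
    X = pd.DataFrame({"i": [1.0] * 4, "dup": [1.0] * 4}, index=list("abcd"))
    with pytest.raises(ValueError, match="rank"):
        DesignSpec(X=X)


# ----------------------------------------------------------------------
# prior estimation
# ----------------------------------------------------------------------

def test_trigamma_inverse_roundtrip():
    from scipy.special import polygamma
    for x in [0.05, 0.5, 2.0, 17.0, 400.0]:
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-8)


def test_prior_recovery_from_scaled_inv_chisq_draws():
    rng = np.random.default_rng(123)
    d0, s02, d = 4.0, 1.0, 4
    s2 = d0 * s02 / rng.chisquare(d0, size=5000) * rng.chisquare(d, size=5000) / d
    d0_hat, s02_hat = estimate_prior(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.15)
    assert s02_hat == pytest.approx(s02, rel=0.15)


def test_prior_degenerate_when_variances_identical():
    d0, s02 = estimate_prior(np.full(50, 2.5), 4)
    assert np.isinf(d0)
    assert s02 == pytest.approx(2.5, rel=1e-6)


def test_prior_scale_equivariance():
    rng = np.random.default_rng(7)
    s2 = rng.chisquare(4, size=2000) / 4
    d0_a, s02_a = estimate_prior(s2, 4)
    d0_b, s02_b = estimate_prior(s2 * 3.0, 4)
    assert d0_b == pytest.approx(d0_a, rel=1e-8)
    assert s02_b == pytest.approx(3.0 * s02_a, rel=1e-8)


def test_prior_rejects_all_zero_variances():
    with pytest.raises(ValueError):
        estimate_prior(np.zeros(20), 4)


# ----------------------------------------------------------------------
# moderated statistics
# ----------------------------------------------------------------------

def _random_fit(seed=1, n_feat=200):
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(n_feat, 6)) * rng.uniform(0.5, 2.0, size=(n_feat, 1))
    return _fit(Y), Y


def test_moderated_t_with_zero_prior_df_is_ordinary_t():
    fit, Y = _random_fit()
    moderate(fit, d0=0.0, s02=1.0)
    de = moderated_t(fit, "diff")
    t_ref, p_ref = stats.ttest_ind(Y[:, 3:], Y[:, :3], axis=1, equal_var=True)
    assert np.allclose(de["t"].to_numpy(), t_ref, atol=1e-10)
    assert np.allclose(de["p"].to_numpy(), p_ref, atol=1e-10)


def test_moderated_t_infinite_prior_df_uses_prior_variance():
    fit, _ = _random_fit()
    moderate(fit, d0=1e12, s02=0.8)
    post = fit.sigma2_post
    assert np.allclose(post, 0.8, atol=1e-6)


def test_shrinkage_lies_between_prior_and_observed():
    fit, _ = _random_fit()
    moderate(fit)
    lo = np.minimum(fit.sigma2, fit.s02)
    hi = np.maximum(fit.sigma2, fit.s02)
    post = fit.sigma2_post
    assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


def test_zero_effect_gives_t_zero_p_one():
    # identical group means -> contrast estimate exactly 0
    fit = _fit([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
    moderate(fit, d0=4.0, s02=0.1)
    de = moderated_t(fit, "diff")
    assert de["logFC"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert de["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert de["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_moderated_F_equals_t_squared_for_single_contrast():
    fit, _ = _random_fit(seed=3)
    moderate(fit)
    t_table = moderated_t(fit, "diff")
    f_table = moderated_F(fit, np.array([[0.0, 1.0]]))
    assert np.allclose(f_table["F"].to_numpy(), t_table["t"].to_numpy() ** 2,
                       atol=1e-10)
    assert np.allclose(f_table["p"].to_numpy(), t_table["p"].to_numpy(), atol=1e-10)


def test_moderated_F_matches_quadratic_form_oracle():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(8), rng.normal(size=8), rng.normal(size=8),
                         rng.normal(size=8)])
    spec = DesignSpec(X=pd.DataFrame(X, columns=list("iabc"),
                                     index=[f"s{j}" for j in range(8)]))
    Y = rng.normal(size=(30, 8))
    fit = _fit(Y, spec)
    moderate(fit)
    C = np.zeros((3, 4))
    C[0, 1] = C[1, 2] = C[2, 3] = 1.0
    f_table = moderated_F(fit, C)
    post = fit.sigma2_post.to_numpy()
    for g in range(30):
        ref = quadratic_form_reference(fit.coef.iloc[g].to_numpy(), C,
                                       fit.xtx_inv, post[g])
        assert f_table["F"].iloc[g] == pytest.approx(ref, abs=1e-10)


def test_limma_oracle_agreement():
    """Moderated t, p and hyperparameters match Bioconductor limma."""
    rng = np.random.default_rng(42)
    n_feat = 60
    Y = rng.normal(10, 1, size=(n_feat, 6))
    Y[:10, 3:] += 2.0
    s2 = 4.0 / rng.chisquare(4, size=n_feat)
    Y = 10 + (Y - 10) * np.sqrt(s2)[:, None]
    df = pd.DataFrame(Y, index=[f"f{i}" for i in range(n_feat)],
                      columns=[f"s{j}" for j in range(6)])

    import tempfile, os
    with tempfile.TemporaryDirectory() as tmp:
        in_path, out_path = os.path.join(tmp, "in.tsv"), os.path.join(tmp, "out.tsv")
        df.to_csv(in_path, sep="\t")
        r_code = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{in_path}", row.names=1))
            design <- cbind(Intercept=1, Group=c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"])
            write.table(out, "{out_path}", sep="\\t", quote=FALSE)
            cat(fit$df.prior, fit$s2.prior)
        """)
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                              text=True, check=True)
        limma = pd.read_csv(out_path, sep="\t")
        d0_ref, s02_ref = map(float, proc.stdout.split())

    fit = _fit(Y)
    moderate(fit)
    assert fit.d0 == pytest.approx(d0_ref, rel=1e-5)
    assert fit.s02 == pytest.approx(s02_ref, rel=1e-5)
    de = moderated_t(fit, "diff")
    assert np.allclose(de["t"].to_numpy(), limma["t"].to_numpy(), atol=1e-8)
    assert np.allclose(de["p"].to_numpy(), limma["p"].to_numpy(), atol=1e-8)


# ----------------------------------------------------------------------
# BH and significance
# ----------------------------------------------------------------------

def test_bh_worked_example():
    out = bh_adjust([0.01, 0.02, 0.03, 0.5])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])


@pytest.mark.parametrize("p", [
    [0.2, 0.2, 0.2],             # all equal stay equal
    [0.123],                     # m = 1 -> unchanged
    [1.0, 0.0, 0.5, 0.5, 0.01],
])
def test_bh_direct_enumeration(p):
    assert np.allclose(bh_adjust(p), bh_reference(p))


def test_bh_matches_statsmodels_on_random_vectors():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(11)
    for _ in range(5):
        p = rng.uniform(size=rng.integers(5, 200))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_mark_significant_needs_both_criteria():
    de = pd.DataFrame({"logFC": [2.0, 0.3, 2.0], "fdr": [0.01, 0.01, 0.2]})
    out = mark_significant(de, SignifConfig())
    assert out["significant"].tolist() == [True, False, False]
    assert (out["fdr"] >= out.get("p", out["fdr"])).all()


# ----------------------------------------------------------------------
# one-tailed enzyme validation
# ----------------------------------------------------------------------

def test_one_tailed_validation_directions():
    design = make_design()
    vals = np.ones((3, len(design)))
    ai = (design["cell_line"] == "AI").to_numpy()
    un = (design["condition"] == "untreated").to_numpy()
    # knocked-in enzyme: clearly higher in AI starved samples
    vals[0, ai & un] = [5.0, 5.2, 5.4]
    vals[0, ~ai & un] = [1.0, 1.1, 1.2]
    # knocked-out enzyme given *higher* AI values: p should be near 1
    vals[1, ai & un] = [5.0, 5.2, 5.4]
    vals[1, ~ai & un] = [1.0, 1.1, 1.2]
    # identical group means -> p = 0.5
    vals[2, ai & un] = [1.0, 2.0, 3.0]
    vals[2, ~ai & un] = [3.0, 2.0, 1.0]
    m = matrix_from(vals, sample_ids=list(design["sample_id"]),
                    feature_ids=["KI", "KO", "FLAT"])
    out = one_tailed_validation(m, design, {"KI": "up", "KO": "down",
                                            "FLAT": "up", "ABSENT": "down"})
    assert out.loc["KI", "p_one_sided"] < 0.05 and out.loc["KI", "passes"]
    assert out.loc["KO", "p_one_sided"] > 0.9
    assert out.loc["FLAT", "p_one_sided"] == pytest.approx(0.5)
    assert not out.loc["ABSENT", "detected"]


# ----------------------------------------------------------------------
# synthetic-data power / FDR behaviour
# ----------------------------------------------------------------------

def test_power_monotone_in_effect_size():
    """Planted |log2FC| 1.5 yields strictly more calls than 0.5 at equal n."""
    from glycophos.containers import design_subset
    from glycophos.preprocess import preprocess_layer
    from glycophos.simulate import SimulationConfig, generate_dataset

    counts = {}
    for amp in (0.5, 1.5):
        cfg = SimulationConfig(n_global=10, n_glyco=10, n_phospho=600, seed=21,
                               serum_amplitude_log2=amp)
        ds = generate_dataset(cfg)
        res = preprocess_layer(ds["matrices"]["phospho"], ds["design"], seed=21)
        de = pairwise_de(res["imputed"],
                         design_subset(ds["design"], cell_line="WT"),
                         "condition", "treated", "untreated")
        counts[amp] = int(de["significant"].sum())
    assert counts[1.5] > counts[0.5]


def test_factorial_F_flags_planted_effects(small_dataset):
    from glycophos.preprocess import preprocess_layer
    res = preprocess_layer(small_dataset["matrices"]["glyco"],
                           small_dataset["design"], seed=5)
    ff = factorial_F(res["imputed"], small_dataset["design"])
    truth = small_dataset["truth"].set_index("feature_id")
    affected = truth.reindex(ff.index)["affected_cell_line"].fillna(False)
    # affected glycopeptides dominate the significant set
    sig = ff["significant"]
    assert sig[affected.to_numpy(bool)].mean() > 0.8
    assert sig[~affected.to_numpy(bool)].mean() < 0.1
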
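"""Reproducible figure-level experiment protocols.

Each ``run_*`` function is a pure function of (config, seed): it generates
its own training and test data from purpose-keyed seed streams, trains the
harmonium, decodes, and returns a JSON-serializable report.  Training and
test batches always come from distinct streams and are therefore disjoint.
"""

from __future__ import annotations

import numpy as np

from ._rng import seed_stream
from .config import config_hash, merge_config
from .decoder import (
    decode_expected_inputs,
    decode_posterior,
    decode_posterior_mean,
    fit_count_calibrator,
    recover_totals,
)
from .harmonium import Harmonium, TrainingSchedule, hidden_code, init_harmonium, train
from .inference import (
    GaussianPosterior,
    _kl_terms,
    center_of_mass,
    coordtrans_posterior,
    decoupled_optimal_covariance,
    flat_prior_proxy,
    info_loss_fractions,
    integration_moments,
)
from .kinematics import ArmModel, forward_kinematics, inverse_kinematics
from .popcode import (
    GainPrior,
    PopulationCode,
    StimulusPrior,
    build_population,
    sample_coordtrans_batch,
    sample_decoupled_batch,
    sample_discrepant_batch,
    sample_integration_batch,
)

__all__ = [
    "integration_setup",
    "train_integration_network",
    "evaluate_integration",
    "run_integration",
    "run_capacity_sweep",
    "run_generalization",
    "run_prior_experiment",
    "run_decoupled",
    "run_hierarchical",
    "run_coordtrans",
]


# ---------------------------------------------------------------------------
# shared plumbing


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def workspace_bounds(arm: ArmModel, n_grid: int = 61) -> np.ndarray:
    """Axis-aligned bounding box of the reachable Cartesian workspace."""
    lims = np.asarray(arm.joint_limits, dtype=float)
    g1 = np.linspace(*lims[0], n_grid)
    g2 = np.linspace(*lims[1], n_grid)
    th = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1).reshape(-1, 2)
    x = forward_kinematics(th, arm)
    return np.stack([x.min(axis=0), x.max(axis=0)], axis=-1)


def integration_setup(cfg: dict):
    """Arm, populations and priors for the standard integration problem."""
    arm = ArmModel(
        link_lengths=tuple(cfg["arm"]["link_lengths"]),
        joint_limits=tuple(map(tuple, cfg["arm"]["joint_limits"])),
    )
    n = cfg["populations"]["units_per_dim"]
    margin = cfg["populations"]["margin_sd"]
    fwhm = cfg["populations"]["fwhm_fraction"]
    pops = {
        "prop": build_population("prop", arm.joint_limits, n, margin, fwhm),
        "vis": build_population("vis", workspace_bounds(arm), n, margin, fwhm),
    }
    gain_priors = {
        name: GainPrior(*cfg["gains"][name]) for name in ("prop", "vis")
    }
    stim_prior = _stimulus_prior(cfg, arm)
    return arm, pops, gain_priors, stim_prior


def _stimulus_prior(cfg: dict, arm: ArmModel) -> StimulusPrior:
    kind = cfg["stimulus_prior"]["kind"]
    if kind != "gaussian-joint":
        return StimulusPrior(kind=kind)
    lims = np.asarray(arm.joint_limits, dtype=float)
    sd = (lims[:, 1] - lims[:, 0]) / cfg["stimulus_prior"]["sd_separation"]
    return StimulusPrior(
        kind="gaussian-joint", mean=lims.mean(axis=1), covariance=np.diag(sd**2)
    )


def _schedule(cfg: dict) -> TrainingSchedule:
    tr = cfg["training"]
    return TrainingSchedule(
        n_vectors=tr["n_vectors"],
        minibatch=tr["minibatch"],
        epochs_per_stage=tr["epochs_per_stage"],
        n_stages=tr["n_stages"],
        lr_w=tr["lr_w"],
        lr_b=tr["lr_b"],
        anneal_factor=tr["anneal_factor"],
        neg_hidden=tr["neg_hidden"],
        pos_hidden=tr["pos_hidden"],
    )


def _train_on_batch(counts: np.ndarray, cfg: dict, seed: int, n_hidden: int | None,
                    rate_cap: float | np.ndarray):
    sched = _schedule(cfg)
    n_vis = counts.shape[1]
    if n_hidden is None:
        n_hidden = n_vis // 2
    model = init_harmonium(
        n_vis,
        n_hidden,
        seed_stream(seed, "init"),
        mean_rates=counts[: min(5000, counts.shape[0])].mean(axis=0),
        weight_sd=cfg["training"]["weight_sd"],
        rate_cap=rate_cap,
        dtype=np.float32 if cfg["training"]["dtype"] == "float32" else np.float64,
    )
    trace = train(model, counts, sched, seed_stream(seed, "gibbs"))
    return model, trace


def train_integration_network(cfg: dict, seed: int, sampler=None):
    """Generate training data and fit the standard two-population harmonium.

    ``sampler(n, rng)`` overrides the data source (prior/decoupled variants);
    it must return a TrialBatch with the standard prop/vis layout.
    """
    arm, pops, gain_priors, stim_prior = integration_setup(cfg)
    rng = seed_stream(seed, "train-data")
    if sampler is None:
        batch = sample_integration_batch(
            cfg["training"]["n_vectors"], stim_prior, gain_priors, arm, pops, rng
        )
    else:
        batch = sampler(cfg["training"]["n_vectors"], rng)
    cap = cfg["training"]["rate_cap_factor"] * max(
        gp.hi for gp in gain_priors.values()
    )
    model, trace = _train_on_batch(
        batch.counts, cfg, seed, cfg["network"]["n_hidden"], cap
    )
    return model, trace, batch.layout, (arm, pops, gain_priors, stim_prior)


def _marginal_stats(errors: np.ndarray) -> dict:
    return {
        "bias": errors.mean(axis=0),
        "cov": np.cov(errors.T),
        "det_cov": float(np.linalg.det(np.atleast_2d(np.cov(errors.T)))),
        "n": int(errors.shape[0]),
    }


def evaluate_integration(
    model: Harmonium,
    layout: dict,
    setup,
    cfg: dict,
    seed: int,
    batch=None,
    with_calibrator: bool = False,
) -> dict:
    """Decode a fresh test batch with all four estimators and score them.

    Estimators: vis-only and prop-only centers of mass (MAP given one
    population), the optimal posterior given both, and the harmonium-based
    posterior decoded from ``n_hidden_samples`` hidden samples.
    """
    arm, pops, gain_priors, stim_prior = setup
    n_test = cfg["testing"]["n_test"]
    rng = seed_stream(seed, "test-data")
    if batch is None:
        batch = sample_integration_batch(
            n_test, stim_prior, gain_priors, arm, pops, rng
        )
    kp = batch.counts_for("prop")
    kv = batch.counts_for("vis")

    com_p = center_of_mass(kp, pops["prop"])
    com_v = center_of_mass(kv, pops["vis"])
    opt_mean, opt_cov, opt_valid = integration_moments(
        kp, kv, stim_prior, arm, pops["prop"], pops["vis"]
    )

    n_samp = cfg["testing"]["n_hidden_samples"]
    vbar = hidden_code(
        model, batch.counts.astype(float), n_samp, seed_stream(seed, "decode")
    )
    mod_mean_est = decode_posterior_mean(model, vbar, pops, layout, "prop")
    mod_mean, mod_cov, mod_valid = decode_posterior(
        model, vbar, pops, layout, arm, stim_prior
    )

    ok = (
        opt_valid
        & mod_valid
        & np.isfinite(com_p).all(axis=-1)
        & np.isfinite(com_v).all(axis=-1)
        & np.isfinite(mod_mean_est).all(axis=-1)
    )
    dropped = int(np.sum(~ok))
    theta = batch.theta[ok]
    com_p, com_v = com_p[ok], com_v[ok]
    opt_mean, opt_cov = opt_mean[ok], opt_cov[ok]
    mod_mean, mod_cov, mod_mean_est = mod_mean[ok], mod_cov[ok], mod_mean_est[ok]
    vbar_ok = vbar[ok]
    kp, kv = kp[ok], kv[ok]

    theta_vis = inverse_kinematics(com_v, arm, clamp=True)
    errors = {
        "vis": theta_vis - theta,
        "prop": com_p - theta,
        "optimal": opt_mean - theta,
        "model": mod_mean_est - theta,
        "model_combined": mod_mean - theta,
    }
    report = {
        "marginal": {k: _marginal_stats(v) for k, v in errors.items()},
        "n_test": int(batch.n_trials),
        "n_dropped": dropped,
        "config_hash": config_hash(cfg),
        "seed": int(seed),
    }

    # covariance-only KL: model posterior vs the fixed average-count posterior
    prior_g = (
        GaussianPosterior("prop", stim_prior.mean, stim_prior.covariance)
        if stim_prior.kind == "gaussian-joint"
        else flat_prior_proxy(arm.joint_limits)
    )
    kl_model = _kl_terms(opt_mean, opt_cov, mod_mean, mod_cov, cov_only=True)
    # fixed baseline: batch-average total counts, per-trial Jacobian at the
    # optimal mean — what a network that learned only the gain prior could do
    from .kinematics import jacobian
    from .inference import _prior_terms

    nbar_p = kp.sum(axis=1).mean()
    nbar_v = kv.sum(axis=1).mean()
    J = jacobian(np.clip(opt_mean, *np.transpose(arm.joint_limits)), arm)
    p0, _ = _prior_terms(stim_prior, 2)
    fix_prec = (
        p0[None]
        + (nbar_p / pops["prop"].sigma_tc**2) * np.eye(2)
        + (nbar_v / pops["vis"].sigma_tc**2) * np.einsum("nji,njk->nik", J, J)
    )
    fix_cov = np.linalg.inv(fix_prec)
    kl_fixed = _kl_terms(opt_mean, opt_cov, opt_mean, fix_cov, cov_only=True)
    report["kl_cov_only"] = {
        "model_mean_nats": float(np.mean(kl_model)),
        "fixed_mean_nats": float(np.mean(kl_fixed)),
    }

    # fractional information loss per gain bin
    frac = info_loss_fractions(opt_mean, opt_cov, mod_mean, mod_cov, prior_g)
    nb = cfg["testing"]["gain_bins"]
    gp, gv = batch.gains["prop"][ok], batch.gains["vis"][ok]
    edges_p = np.linspace(gain_priors["prop"].lo, gain_priors["prop"].hi, nb + 1)
    edges_v = np.linspace(gain_priors["vis"].lo, gain_priors["vis"].hi, nb + 1)
    bins = np.full((nb, nb), np.nan)
    for i in range(nb):
        for j in range(nb):
            sel = (
                (gp >= edges_p[i])
                & (gp <= edges_p[i + 1])
                & (gv >= edges_v[j])
                & (gv <= edges_v[j + 1])
            )
            if np.any(sel):
                bins[i, j] = float(np.mean(frac[sel]))
    report["info_loss"] = {
        "per_gain_bin": bins,
        "max_bin": float(np.nanmax(bins)),
        "mean": float(np.mean(frac)),
    }

    # total-count recovery
    true_tot = np.stack([kp.sum(axis=1), kv.sum(axis=1)], axis=-1)
    raw_tot = recover_totals(model, vbar_ok, layout)
    half = raw_tot.shape[0] // 2
    r2 = {}
    if with_calibrator and half > 50:
        if cfg["calibrator"]["use_hidden"]:
            feats = np.concatenate([raw_tot, vbar_ok], axis=1)
        else:
            feats = raw_tot
        calib = fit_count_calibrator(
            feats[:half], true_tot[:half], seed=seed, trial_ids=np.arange(half),
            hidden_units=cfg["calibrator"]["hidden_units"],
        )
        cal_tot = calib.predict(feats[half:])
        r2["calibrated"] = [
            _r2(true_tot[half:, i], cal_tot[:, i]) for i in range(2)
        ]
        r2["raw"] = [_r2(true_tot[half:, i], raw_tot[half:, i]) for i in range(2)]
    else:
        r2["raw"] = [_r2(true_tot[:, i], raw_tot[:, i]) for i in range(2)]
    report["total_count_r2"] = r2
    return _jsonable(report)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def run_integration(cfg: dict | None = None, seed: int = 0) -> dict:
    """Train the standard network and evaluate all four estimators."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    model, trace, layout, setup = train_integration_network(cfg, seed)
    report = evaluate_integration(
        model, layout, setup, cfg, seed, with_calibrator=True
    )
    report["training"] = {
        "deviance_first": trace["deviance"][0],
        "deviance_last": trace["deviance"][-1],
        "cap_fraction_last": trace["cap_fraction"][-1],
    }
    return report


def _is_merged(cfg) -> bool:
    return isinstance(cfg, dict) and set(cfg) == set(merge_config(None))


# ---------------------------------------------------------------------------
# capacity / noise sweep


def run_capacity_sweep(
    hidden_sizes, sample_counts, cfg: dict | None = None, seed: int = 0
) -> dict:
    """Error-covariance determinant as a function of capacity and hidden noise."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    arm, pops, gain_priors, stim_prior = integration_setup(cfg)
    test = sample_integration_batch(
        cfg["testing"]["n_test"],
        stim_prior,
        gain_priors,
        arm,
        pops,
        seed_stream(seed, "test-data"),
    )
    opt_mean, opt_cov, opt_ok = integration_moments(
        test.counts_for("prop"), test.counts_for("vis"), stim_prior, arm,
        pops["prop"], pops["vis"],
    )
    det_opt = float(
        np.linalg.det(np.cov((opt_mean[opt_ok] - test.theta[opt_ok]).T))
    )
    rows = []
    for h in hidden_sizes:
        model, _, layout, _ = train_integration_network(
            {**cfg, "network": {"n_hidden": int(h)}}, seed
        )
        for n_s in list(sample_counts) + [None]:
            vbar = hidden_code(
                model,
                test.counts.astype(float),
                n_s,
                seed_stream(seed + 1000 + (n_s or 0), "decode"),
            )
            est = decode_posterior_mean(model, vbar, pops, layout, "prop")
            ok = np.isfinite(est).all(axis=-1)
            err = est[ok] - test.theta[ok]
            rows.append(
                {
                    "n_hidden": int(h),
                    "n_samples": n_s,
                    "det_error_cov": float(np.linalg.det(np.cov(err.T))),
                }
            )
    return _jsonable(
        {
            "rows": rows,
            "det_optimal": det_opt,
            "config_hash": config_hash(cfg),
            "seed": int(seed),
        }
    )


# ---------------------------------------------------------------------------
# generalization: input discrepancy and gain modulation


def run_generalization(
    cfg: dict | None = None,
    seed: int = 0,
    k_sd_list=None,
    gain_ranges=(),
) -> dict:
    """Test a single trained network off its training distribution."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    model, _, layout, setup = train_integration_network(cfg, seed)
    arm, pops, gain_priors, stim_prior = setup
    if k_sd_list is None:
        k_sd_list = cfg["discrepancy"]["k_sd_list"]
    direction = np.asarray(cfg["discrepancy"]["direction"], dtype=float)
    n_test = cfg["testing"]["n_test"]
    out = {"discrepancy": [], "gains": [], "config_hash": config_hash(cfg)}

    for k_sd in [0.0] + list(k_sd_list):
        batch = sample_discrepant_batch(
            n_test, k_sd, direction, stim_prior, gain_priors, arm, pops,
            seed_stream(seed + int(k_sd * 100), "test-data"),
        )
        stats = _model_vs_optimal(model, layout, setup, cfg, seed, batch)
        stats["k_sd"] = float(k_sd)
        out["discrepancy"].append(stats)

    for gains in gain_ranges:
        gp = {name: GainPrior(*gains[name]) for name in ("prop", "vis")}
        batch = sample_integration_batch(
            n_test, stim_prior, gp, arm, pops,
            seed_stream(seed + 7919, "test-data"),
        )
        stats = _model_vs_optimal(model, layout, setup, cfg, seed, batch)
        stats["gains"] = gains
        out["gains"].append(stats)
    return _jsonable(out)


def _model_vs_optimal(model, layout, setup, cfg, seed, batch) -> dict:
    arm, pops, gain_priors, stim_prior = setup
    kp, kv = batch.counts_for("prop"), batch.counts_for("vis")
    opt_mean, opt_cov, opt_ok = integration_moments(
        kp, kv, stim_prior, arm, pops["prop"], pops["vis"]
    )
    vbar = hidden_code(
        model,
        batch.counts.astype(float),
        cfg["testing"]["n_hidden_samples"],
        seed_stream(seed, "decode"),
    )
    est = decode_posterior_mean(model, vbar, pops, layout, "prop")
    ok = opt_ok & np.isfinite(est).all(axis=-1)
    err_o = opt_mean[ok] - batch.theta[ok]
    err_m = est[ok] - batch.theta[ok]
    return {
        "optimal": _marginal_stats(err_o),
        "model": _marginal_stats(err_m),
        "mean_gap": float(np.linalg.norm(err_m.mean(0) - err_o.mean(0))),
    }


# ---------------------------------------------------------------------------
# non-flat prior


def run_prior_experiment(cfg: dict | None = None, seed: int = 0) -> dict:
    """Train with a tight Gaussian stimulus prior and test prior encoding."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    cfg = {**cfg, "stimulus_prior": {**cfg["stimulus_prior"], "kind": "gaussian-joint"}}
    model, trace, layout, setup = train_integration_network(cfg, seed)
    arm, pops, gain_priors, stim_prior = setup
    report = evaluate_integration(model, layout, setup, cfg, seed)

    # conditional bias toward the prior mean at stimuli 8 prior-sd out
    sd = np.sqrt(np.diag(stim_prior.covariance))
    mu0 = np.asarray(stim_prior.mean)
    probes = [mu0 + 8 * sd * d for d in
              (np.array([1, 0]), np.array([-1, 0]), np.array([0, 1]), np.array([0, -1]))]
    rng = seed_stream(seed, "test-data")
    n_rep = 400
    toward = []
    for s in probes:
        gp = gain_priors["prop"].sample(rng, n_rep)
        gv = gain_priors["vis"].sample(rng, n_rep)
        from .popcode import mean_rates  # local import avoids cycle at top

        kp = rng.poisson(mean_rates(np.broadcast_to(s, (n_rep, 2)), gp, pops["prop"]))
        kv = rng.poisson(
            mean_rates(
                np.broadcast_to(forward_kinematics(s, arm), (n_rep, 2)),
                gv,
                pops["vis"],
            )
        )
        counts = np.concatenate([kp, kv], axis=1).astype(float)
        vbar = hidden_code(
            model, counts, cfg["testing"]["n_hidden_samples"], seed_stream(seed, "decode")
        )
        est = decode_posterior_mean(model, vbar, pops, layout, "prop")
        est = est[np.isfinite(est).all(axis=-1)]
        # positive projection = conditional mean pulled toward the prior mean
        toward.append(float(np.mean((est - s) @ (mu0 - s)) / np.linalg.norm(mu0 - s)))
    report["conditional_pull_toward_prior"] = toward
    report["prior_sd"] = sd
    return _jsonable(report)


# ---------------------------------------------------------------------------
# sometimes-decoupled inputs


def run_decoupled(cfg: dict | None = None, seed: int = 0) -> dict:
    """Train on sometimes-decoupled data with an explicit toggle unit."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    arm, pops, gain_priors, stim_prior = integration_setup(cfg)
    p_couple = cfg["decoupled"]["p_couple"]

    def sampler(n, rng):
        return sample_decoupled_batch(
            n, p_couple, stim_prior, gain_priors, arm, pops, rng
        )

    model, _, layout, setup = train_integration_network(cfg, seed, sampler=sampler)
    test = sampler(cfg["testing"]["n_test"], seed_stream(seed, "test-data"))
    kp, kv = test.counts_for("prop"), test.counts_for("vis")
    coupled = np.asarray(test.meta["coupled"])

    vbar = hidden_code(
        model,
        test.counts.astype(float),
        cfg["testing"]["n_hidden_samples"],
        seed_stream(seed, "decode"),
    )
    est = decode_posterior_mean(model, vbar, pops, layout, "prop")
    ok = np.isfinite(est).all(axis=-1)
    err_model = est[ok] - test.theta[ok]

    # condition-aware optimal: integrate when coupled, prop-only otherwise
    opt_mean, _, opt_ok = integration_moments(
        kp, kv, stim_prior, arm, pops["prop"], pops["vis"]
    )
    com_p = center_of_mass(kp, pops["prop"])
    sel_c = coupled & opt_ok
    sel_u = ~coupled & np.isfinite(com_p).all(axis=-1)
    cov_coupled = np.cov((opt_mean[sel_c] - test.theta[sel_c]).T)
    cov_uncoupled = np.cov((com_p[sel_u] - test.theta[sel_u]).T)
    cov_opt = decoupled_optimal_covariance(cov_coupled, cov_uncoupled, p_couple)

    report = {
        "model": _marginal_stats(err_model),
        "optimal_mixture_cov": cov_opt,
        "det_optimal_mixture": float(np.linalg.det(cov_opt)),
        "det_coupled_only": float(np.linalg.det(cov_coupled)),
        "model_coupled": _marginal_stats(est[ok & coupled] - test.theta[ok & coupled]),
        "model_uncoupled": _marginal_stats(
            est[ok & ~coupled] - test.theta[ok & ~coupled]
        ),
        "p_couple": float(p_couple),
        "empirical_couple_fraction": float(np.mean(coupled)),
        "config_hash": config_hash(cfg),
        "seed": int(seed),
    }
    return _jsonable(report)


# ---------------------------------------------------------------------------
# hierarchical two-stage integration


def run_hierarchical(cfg: dict | None = None, seed: int = 0) -> dict:
    """Stage-2 harmonium on [stage-1 hidden counts, a third population]."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    model1, _, layout1, setup = train_integration_network(cfg, seed)
    arm, pops, gain_priors, stim_prior = setup
    n_samp = cfg["testing"]["n_hidden_samples"]
    pop2 = build_population(
        "prop2",
        arm.joint_limits,
        cfg["populations"]["units_per_dim"],
        cfg["populations"]["margin_sd"],
        cfg["populations"]["fwhm_fraction"],
    )
    gain2 = GainPrior(*cfg["hierarchical"]["gain_prop2"])
    count_cap = cfg["hierarchical"]["hidden_count_cap"]

    activity = cfg["hierarchical"]["stage1_activity"]

    def stage2_data(n, rng, tag_seed):
        batch = sample_integration_batch(n, stim_prior, gain_priors, arm, pops, rng)
        ph = hidden_code(model1, batch.counts.astype(float), None)
        if activity == "means":
            h_counts = n_samp * ph
        else:
            h_counts = seed_stream(tag_seed, "decode").binomial(n_samp, ph)
        k2 = rng.poisson(
            _rates(batch.theta, gain2.sample(rng, n), pop2)
        )
        visible = np.concatenate([h_counts, k2], axis=1)
        layout2 = {
            "hidden1": (0, h_counts.shape[1]),
            "prop2": (h_counts.shape[1], visible.shape[1]),
        }
        return batch, k2, visible, layout2

    tr_batch, _, vis2_train, layout2 = stage2_data(
        cfg["training"]["n_vectors"], seed_stream(seed, "train-data"), seed + 1
    )
    cap_vec = np.concatenate(
        [
            np.full(layout2["hidden1"][1], float(count_cap)),
            np.full(
                layout2["prop2"][1] - layout2["prop2"][0],
                cfg["training"]["rate_cap_factor"] * gain2.hi,
            ),
        ]
    )
    model2, _ = _train_on_batch(
        vis2_train, cfg, seed + 1, cfg["network"]["n_hidden"], cap_vec
    )

    test, k2_test, vis2_test, _ = stage2_data(
        cfg["testing"]["n_test"], seed_stream(seed, "test-data"), seed + 2
    )
    kp, kv = test.counts_for("prop"), test.counts_for("vis")

    # stage-1 estimate (integrated representation 1)
    vbar1 = hidden_code(
        model1, test.counts.astype(float), n_samp, seed_stream(seed, "decode")
    )
    est1 = decode_posterior_mean(model1, vbar1, pops, layout1, "prop")

    # stage-2 estimate: decode down both generative maps to the prop1 code
    vbar2 = hidden_code(
        model2, vis2_test.astype(float), n_samp, seed_stream(seed + 3, "decode")
    )
    parts2 = decode_expected_inputs(model2, vbar2, layout2)
    vbar1_rec = np.clip(parts2["hidden1"] / float(n_samp), 0.0, 1.0)
    parts1 = decode_expected_inputs(model1, vbar1_rec, layout1)
    est2 = center_of_mass(parts1["prop"], pops["prop"])
    # full posterior combination across all three decoded cues
    est2c, _, ok2c = integration_moments(
        parts1["prop"], parts1["vis"], stim_prior, arm,
        pops["prop"], pops["vis"],
        extra_joint_cues=[(parts2["prop2"], pop2)],
    )

    # optima
    opt2_mean, _, ok2 = integration_moments(
        kp, kv, stim_prior, arm, pops["prop"], pops["vis"]
    )
    opt3_mean, _, ok3 = integration_moments(
        kp, kv, stim_prior, arm, pops["prop"], pops["vis"],
        extra_joint_cues=[(k2_test, pop2)],
    )
    ok = (
        ok2 & ok3 & ok2c
        & np.isfinite(est1).all(axis=-1)
        & np.isfinite(est2).all(axis=-1)
    )
    th = test.theta[ok]
    report = {
        "stage1_model": _marginal_stats(est1[ok] - th),
        "stage2_model": _marginal_stats(est2[ok] - th),
        "stage2_model_combined": _marginal_stats(est2c[ok] - th),
        "optimal_two_cue": _marginal_stats(opt2_mean[ok] - th),
        "optimal_three_cue": _marginal_stats(opt3_mean[ok] - th),
        "config_hash": config_hash(cfg),
        "seed": int(seed),
    }
    return _jsonable(report)


def _rates(stimulus, gain, pop):
    from .popcode import mean_rates

    return mean_rates(stimulus, gain, pop)


# ---------------------------------------------------------------------------
# coordinate transformation


def coordtrans_setup(cfg: dict):
    arm = ArmModel(
        mode="cosine-1d",
        joint_limits=tuple(cfg["arm"]["joint_limits_1d"]),
        link_1d=cfg["arm"]["link_1d"],
    )
    ct = cfg["coordtrans"]
    n = ct["units_per_pop"]
    margin = cfg["populations"]["margin_sd"]
    fwhm = cfg["populations"]["fwhm_fraction"]
    xr = ct["retinal_range"]
    ey = ct["eye_range"]
    # vis and eye tile exactly the spaces they are sampled in; prop tiles the
    # full joint range, whose image (X_b) spans the sum of the two ranges
    pops = {
        "prop": build_population("prop", [tuple(np.sort(arm.joint_limits))], n, margin, fwhm),
        "vis": build_population("vis", [tuple(xr)], n, margin, fwhm),
        "eye": build_population("eye", [tuple(ey)], n, margin, fwhm),
    }
    gains = {
        "prop": GainPrior(*ct["gain_prop"]),
        "vis": GainPrior(*ct["gain_vis"]),
        "eye": GainPrior(*ct["gain_eye"]),
    }
    ranges = {"retinal": tuple(xr), "eye": tuple(ey)}
    return arm, pops, gains, ranges


def run_coordtrans(cfg: dict | None = None, seed: int = 0) -> dict:
    """Learn the coordinate transformation H_b = H_r + E and score MSEs."""
    cfg = merge_config(cfg) if not _is_merged(cfg) else cfg
    ct = cfg["coordtrans"]
    cfg = {**cfg, "training": {**cfg["training"], "lr_w": ct["lr_w"],
                               "lr_b": ct["lr_b"], "n_stages": ct["n_stages"]}}
    arm, pops, gains, ranges = coordtrans_setup(cfg)
    train_batch = sample_coordtrans_batch(
        cfg["training"]["n_vectors"], ranges, gains, arm, pops,
        seed_stream(seed, "train-data"),
    )
    cap = cfg["training"]["rate_cap_factor"] * max(g.hi for g in gains.values())
    model, trace = _train_on_batch(
        train_batch.counts, cfg, seed, cfg["coordtrans"]["n_hidden"], cap
    )
    layout = train_batch.layout

    test = sample_coordtrans_batch(
        cfg["testing"]["n_test"], ranges, gains, arm, pops,
        seed_stream(seed, "test-data"),
    )
    xb_true = test.x[:, 0]
    kt, kv, ke = (test.counts_for(n) for n in ("prop", "vis", "eye"))

    opt_mean, opt_var, opt_ok = coordtrans_posterior(kt, kv, ke, pops, arm)
    com_t = center_of_mass(kt, pops["prop"])[:, 0]
    com_v = center_of_mass(kv, pops["vis"])[:, 0]
    com_e = center_of_mass(ke, pops["eye"])[:, 0]
    prop_only = arm.link_1d * np.cos(com_t)
    vis_eye = com_v + com_e

    vbar = hidden_code(
        model,
        test.counts.astype(float),
        cfg["testing"]["n_hidden_samples"],
        seed_stream(seed, "decode"),
    )
    parts = decode_expected_inputs(model, vbar, layout)
    mod_mean, mod_var, mod_ok = coordtrans_posterior(
        parts["prop"], parts["vis"], parts["eye"], pops, arm
    )
    ok = (
        opt_ok
        & mod_ok
        & np.isfinite(com_t)
        & np.isfinite(com_v)
        & np.isfinite(com_e)
    )

    def mse(est):
        return float(np.mean((est[ok] - xb_true[ok]) ** 2))

    report = {
        "mse": {
            "model": mse(mod_mean),
            "optimal": mse(opt_mean),
            "prop_only": mse(prop_only),
            "vis_eye": mse(vis_eye),
        },
        "n_visible": int(test.counts.shape[1]),
        "n_hidden": int(model.n_hidden),
        "n_dropped": int(np.sum(~ok)),
        "deviance_last": trace["deviance"][-1],
        "config_hash": config_hash(cfg),
        "seed": int(seed),
    }
    return _jsonable(report)
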
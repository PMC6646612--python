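"""Simulate -> measure -> EFI -> analyze orchestration.

Each stage reads/writes plain CSV/JSON/YAML under a run directory and records
a manifest (config snapshot, seed, stage timestamps, file paths, package
version).  A single global seed is fanned out to per-stage, per-subject
substreams so stages can be re-run independently without perturbing others.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import efi as efi_mod
from . import psychophysics as psy
from . import stats as st
from .synthetic_cochlea import (
    CHANNEL_TABLE_COLUMNS,
    CohortConfig,
    ListenerParams,
    VirtualEar,
    generate_cohort,
    load_channel_table,
    write_cohort,
)
from .efi import EFIMatrix, LadderNetwork

logger = logging.getLogger("enisim")

MANIFEST_NAME = "manifest.json"

# stage offsets added to the global seed when spawning substreams
_STAGE_KEYS = {"simulate": 0, "measure": 1, "efi": 2}


class UserError(ValueError):
    """Invalid input or configuration attributable to the caller."""


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _load_manifest(outdir: Path) -> dict:
    path = outdir / MANIFEST_NAME
    if path.exists():
        return json.loads(path.read_text())
    return {"version": __version__, "stages": {}}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    manifest["version"] = __version__
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, default=str))


def _stage_rng_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))


def cmd_simulate(config: CohortConfig | str | Path | None, seed: int, outdir: str | Path) -> dict:
    """Generate a cohort and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = CohortConfig()
    elif not isinstance(config, CohortConfig):
        try:
            config = CohortConfig.from_yaml(config)
        except (yaml.YAMLError, TypeError, ValueError) as exc:
            raise UserError(f"malformed config: {exc}") from exc
    config = dataclasses.replace(config, seed=seed)
    try:
        config.validate()
    except ValueError as exc:
        raise UserError(str(exc)) from exc
    ears = generate_cohort(config)
    paths = write_cohort(ears, outdir, config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest = _load_manifest(outdir)
    manifest["seed"] = seed
    manifest["config"] = config.to_dict()
    manifest["stages"]["simulate"] = {"time": _utcnow(), "outputs": paths}
    _save_manifest(outdir, manifest)
    logger.info("simulated %d subjects x %d electrodes", config.n_subjects, config.n_electrodes)
    return paths


def _reload_cohort(outdir: Path) -> tuple[CohortConfig, list[VirtualEar]]:
    cfg_path = outdir / "config.yaml"
    if not cfg_path.exists():
        raise UserError(f"no cohort found in {outdir} (missing config.yaml); run simulate first")
    config = CohortConfig.from_yaml(cfg_path)
    return config, generate_cohort(config)


def cmd_measure(outdir: str | Path, deterministic_observer: bool = False) -> dict:
    """Run the threshold procedures on every subject.

    Staircases (both polarities, every intracochlear channel) and the sweep
    (channels 2..n-1) produce a measured channel table merged with the latent
    truth for diagnostics.  With ``deterministic_observer`` the psychometric
    slope is zeroed, giving the procedures' noiseless behaviour.
    """
    outdir = Path(outdir)
    config, ears = _reload_cohort(outdir)
    ss = _stage_rng_seed(config.seed, "measure")
    subject_seeds = ss.spawn(len(ears))

    rows = []
    raw = []
    for ear, seq in zip(ears, subject_seeds):
        rng = np.random.default_rng(seq)
        kwargs = dict(slope_db=0.0, false_alarm=0.0, lapse=0.0) if deterministic_observer else {}
        listener = psy.ListenerModel(ear, **kwargs)
        n = ear.n_electrodes
        est_aca = np.full(n, np.nan)
        est_cac = np.full(n, np.nan)
        reasons = [""] * n
        for ch in range(1, n + 1):
            for pol, dest in (("ACA", est_aca), ("CAC", est_cac)):
                stim = psy.monopolar_stimulus(pol, ch)
                est = psy.estimate_threshold_staircase(listener, stim, rng)
                dest[ch - 1] = est.threshold_db
                if est.is_missing and not reasons[ch - 1]:
                    reasons[ch - 1] = est.missing_reason or "missing"
        sweep = psy.run_sweep(listener, rng)
        est_sqp = np.full(n, np.nan)
        est_sqp[sweep.channels - 1] = sweep.thresholds_db
        for run_idx, track in enumerate(sweep.trajectories):
            for c, a, pos, level, resp in track:
                raw.append(
                    dict(subject=ear.subject_id, procedure="sweep", run=run_idx,
                         channel=c, alpha=a, level_db=level, response=int(resp))
                )
        for e in range(n):
            site = ear.sites[e]
            rows.append(
                dict(
                    subject_id=ear.subject_id,
                    electrode=e + 1,
                    emd_mm=site.emd_mm,
                    scalar_location=site.scalar_location,
                    r_long_ohm=np.nan,  # filled from the EFI stage
                    t_aca_db=est_aca[e],
                    t_cac_db=est_cac[e],
                    t_sqp_db=est_sqp[e],
                    pe_db=est_aca[e] - est_cac[e],
                    missing_reason=reasons[e],
                    latent_t_aca_db=ear.t_aca_db[e],
                    latent_t_cac_db=ear.t_cac_db[e],
                    latent_t_sqp_db=ear.t_sqp_db[e],
                    latent_pe_db=ear.pe_db[e],
                )
            )
    table = pd.DataFrame(rows)
    # keep the latent local resistance in the measured table until the EFI
    # stage replaces it with the inverted estimate
    latent = load_channel_table(outdir / "cohort.csv")
    table["r_long_ohm"] = latent["r_long_ohm"].to_numpy()
    measured_path = outdir / "measured.csv"
    with open(measured_path, "w") as fh:
        fh.write(f"# seed={config.seed} stage=measure\n")
        table.to_csv(fh, index=False, float_format="%.8g")
    tracks_path = outdir / "raw_tracks.csv"
    pd.DataFrame(raw).to_csv(tracks_path, index=False, float_format="%.6g")
    manifest = _load_manifest(outdir)
    manifest["stages"]["measure"] = {
        "time": _utcnow(),
        "outputs": {"measured_csv": str(measured_path), "raw_tracks_csv": str(tracks_path)},
        "deterministic_observer": deterministic_observer,
    }
    _save_manifest(outdir, manifest)
    return {"measured_csv": str(measured_path), "raw_tracks_csv": str(tracks_path)}


def _local_from_network(net: LadderNetwork) -> np.ndarray:
    from .synthetic_cochlea import _local_r_long

    return _local_r_long(net.r_long, net.n)


def cmd_efi(outdir: str | Path, noise: float = 0.0) -> dict:
    """Forward-model, optionally perturb, and invert every subject's EFI.

    ``noise`` is the multiplicative relative noise SD applied entry-wise to
    the forward matrices before inversion.  The inverted per-electrode local
    R_long replaces the resistance column of the measured table (when one
    exists) and is written alongside the fitted networks.
    """
    outdir = Path(outdir)
    if noise < 0:
        raise UserError("noise must be >= 0")
    config, ears = _reload_cohort(outdir)
    ss = _stage_rng_seed(config.seed, "efi")
    subject_seeds = ss.spawn(len(ears))
    efi_dir = outdir / "efi"
    efi_dir.mkdir(exist_ok=True)
    records = []
    for ear, seq in zip(ears, subject_seeds):
        rng = np.random.default_rng(seq)
        matrix = efi_mod.forward_efi(ear.network)
        z = matrix.z.copy()
        if noise > 0:
            z = z * (1.0 + noise * rng.standard_normal(z.shape))
            z = np.abs(z)
        noisy = EFIMatrix(z=z, current_ua=matrix.current_ua)
        efi_mod.write_efi_csv(noisy, efi_dir / f"{ear.subject_id}.csv")
        fitted, diag = efi_mod.solve_network(noisy)
        fitted.to_json(efi_dir / f"{ear.subject_id}_network.json")
        local = _local_from_network(fitted)
        true_local = _local_from_network(ear.network)
        for e in range(ear.n_electrodes):
            records.append(
                dict(
                    subject_id=ear.subject_id,
                    electrode=e + 1,
                    r_long_est_ohm=float(local[e]),
                    r_long_true_ohm=float(true_local[e]),
                    fit_converged=diag.converged,
                    weighted_residual=diag.weighted_residual,
                )
            )
    est = pd.DataFrame(records)
    est_path = efi_dir / "efi_estimates.csv"
    est.to_csv(est_path, index=False, float_format="%.8g")

    measured_path = outdir / "measured.csv"
    if measured_path.exists():
        table = pd.read_csv(measured_path, comment="#")
        merged = table.drop(columns=["r_long_ohm"]).merge(
            est[["subject_id", "electrode", "r_long_est_ohm"]],
            on=["subject_id", "electrode"],
        )
        merged = merged.rename(columns={"r_long_est_ohm": "r_long_ohm"})
        merged = merged[
            [c for c in table.columns if c in merged.columns]
            + [c for c in merged.columns if c not in table.columns]
        ]
        with open(measured_path, "w") as fh:
            fh.write(f"# seed={config.seed} stage=efi noise={noise}\n")
            merged.to_csv(fh, index=False, float_format="%.8g")
    manifest = _load_manifest(outdir)
    manifest["stages"]["efi"] = {
        "time": _utcnow(),
        "noise": noise,
        "outputs": {"efi_estimates_csv": str(est_path)},
    }
    _save_manifest(outdir, manifest)
    return {"efi_estimates_csv": str(est_path)}


def cmd_analyze(outdir: str | Path, table_path: str | Path | None = None) -> dict:
    """Run the statistical pipeline on a channel table and write reports."""
    outdir = Path(outdir)
    if table_path is None:
        table_path = outdir / "measured.csv"
        if not Path(table_path).exists():
            table_path = outdir / "cohort.csv"
    table = load_channel_table(table_path)
    table = table[table["scalar_location"] != "extracochlear"].copy()
    table = st.polarity_effect(table)
    if len(table.dropna(subset=["pe_db", "t_sqp_db"])) == 0:
        raise UserError("empty table: no rows with both polarity effect and sQP threshold")
    table["log_r_long"] = np.log10(table["r_long_ohm"])

    report_dir = Path(outdir) / "analysis"
    report_dir.mkdir(parents=True, exist_ok=True)

    # repeated-measures correlations: PE-EMD, PE-logR, sQP-PE trio
    raw_alpha, rep_alpha = st.adjust_alpha(3)
    rmcorrs = {}
    for name, xcol, ycol in (
        ("pe_vs_emd", "emd_mm", "pe_db"),
        ("pe_vs_log_r_long", "log_r_long", "pe_db"),
        ("sqp_vs_pe", "pe_db", "t_sqp_db"),
        ("sqp_vs_emd", "emd_mm", "t_sqp_db"),
        ("sqp_vs_log_r_long", "log_r_long", "t_sqp_db"),
    ):
        sub = table.dropna(subset=[xcol, ycol])
        try:
            res = st.rmcorr(sub[xcol], sub[ycol], sub["subject_id"])
            rmcorrs[name] = dict(
                r_rm=res.r_rm, df=res.df, ci95=list(res.ci95), p=res.p,
                n_obs=res.n_obs, n_subjects=res.n_subjects,
            )
        except ValueError as exc:
            rmcorrs[name] = dict(error=str(exc))
    rmcorr_payload = {
        "bonferroni": {"comparisons": 3, "adjusted_alpha": raw_alpha,
                       "adjusted_alpha_reported": rep_alpha},
        "correlations": rmcorrs,
    }
    (report_dir / "rmcorr.json").write_text(json.dumps(rmcorr_payload, indent=1))

    comparison = st.build_model_sequence(table)
    comparison.as_frame().to_csv(report_dir / "model_comparison.csv", index=False)
    full = comparison.full_reml
    marg, cond = st.pseudo_r2(full)
    fit_payload = dict(
        coefficients={n: {"estimate": float(b), "se": float(s)}
                      for n, b, s in zip(full.fe_names, full.beta, full.se)},
        variance_components=dict(var_u=full.var_u, var_e=full.var_e),
        loglik_reml=full.loglik_reml,
        loglik_ml=full.loglik_ml,
        f_tests=[dataclasses.asdict(f) for f in full.f_tests],
        pseudo_r2=dict(marginal=marg, conditional=cond),
        n_obs=full.n_obs,
        n_subjects=full.n_groups,
    )
    try:
        contrasts = st.scalar_pairwise_contrasts(full)
        fit_payload["tukey_scalar_contrasts"] = [dataclasses.asdict(c) for c in contrasts]
    except ValueError:
        pass
    (report_dir / "full_model.json").write_text(json.dumps(fit_payload, indent=1))

    per_subj = st.per_subject_correlations(table)
    per_subj.to_csv(report_dir / "per_subject_correlations.csv", index=False,
                    float_format="%.6g")
    groups = st.split_groups(table, per_subj)
    groups_payload = dict(
        cutoff=groups.cutoff,
        labels=groups.labels.to_dict(),
        rmcorr_strong=None if groups.rmcorr_strong is None else dict(
            r_rm=groups.rmcorr_strong.r_rm, df=groups.rmcorr_strong.df,
            p=groups.rmcorr_strong.p),
        rmcorr_weak=None if groups.rmcorr_weak is None else dict(
            r_rm=groups.rmcorr_weak.r_rm, df=groups.rmcorr_weak.df,
            p=groups.rmcorr_weak.p),
        notes=groups.notes,
    )
    (report_dir / "groups.json").write_text(json.dumps(groups_payload, indent=1))

    # duration regression on subject means of PE over all available channels
    cfg_path = Path(outdir) / "config.yaml"
    duration_payload = None
    if cfg_path.exists():
        config, ears = _reload_cohort(Path(outdir))
        durations = {e.subject_id: e.duration_of_deafness_years for e in ears}
        means = table.dropna(subset=["pe_db"]).groupby("subject_id")["pe_db"].mean()
        common = [s for s in means.index if s in durations]
        if len(common) >= 3:
            reg = st.duration_regression(
                means.loc[common].to_numpy(), [durations[s] for s in common]
            )
            duration_payload = dataclasses.asdict(reg)
            duration_payload["df"] = list(duration_payload["df"])
            (report_dir / "duration_regression.json").write_text(
                json.dumps(duration_payload, indent=1)
            )

    lines = [
        "Electrode-neuron interface analysis report",
        "==========================================",
        f"rows analysed: {len(table)}",
        "",
        f"Repeated-measures correlations (3 planned comparisons, Bonferroni "
        f"adjusted alpha = {rep_alpha}):",
    ]
    for name in ("sqp_vs_emd", "sqp_vs_log_r_long", "sqp_vs_pe"):
        r = rmcorrs.get(name, {})
        if "r_rm" in r:
            lines.append(
                f"  {name}: r_rm({r['df']}) = {r['r_rm']:.3f}, p = {r['p']:.4g}"
            )
    for name in ("pe_vs_emd", "pe_vs_log_r_long"):
        r = rmcorrs.get(name, {})
        if "r_rm" in r:
            lines.append(
                f"  {name}: r_rm({r['df']}) = {r['r_rm']:.3f}, p = {r['p']:.4g}"
            )
    lines += ["", "AICc model sequence (ML likelihoods):"]
    for i, s in enumerate(comparison.steps):
        mark = " <- selected" if i == comparison.selected else ""
        lines.append(f"  {s.label}: AICc = {s.aicc:.2f}{mark}")
    lines += [
        "",
        f"Full model (REML): R2_marginal = {marg:.2f}, R2_conditional = {cond:.2f}",
    ]
    for f in full.f_tests:
        lines.append(
            f"  {f.term}: F({f.df_num}, {f.df_den:.1f}) = {f.fstat:.2f}, p = {f.p:.4g}"
        )
    if duration_payload is not None:
        lines += [
            "",
            f"Duration of deafness vs mean PE: R2 = {duration_payload['r2']:.2f}, "
            f"adj R2 = {duration_payload['adjusted_r2']:.2f}, "
            f"F(1, {duration_payload['df'][1]}) = {duration_payload['fstat']:.2f}, "
            f"p = {duration_payload['p']:.3g}, slope = {duration_payload['slope']:.3f}",
        ]
    report_txt = report_dir / "report.txt"
    report_txt.write_text("\n".join(lines) + "\n")

    manifest = _load_manifest(Path(outdir))
    manifest["stages"]["analyze"] = {
        "time": _utcnow(),
        "inputs": {"table": str(table_path)},
        "outputs": {"report_dir": str(report_dir)},
    }
    _save_manifest(Path(outdir), manifest)
    return {"report_dir": str(report_dir), "report_txt": str(report_txt)}


def cmd_report(config, seed: int, outdir: str | Path, noise: float = 0.0) -> dict:
    """Full chain: simulate, measure, EFI, analyze; returns the report paths."""
    cmd_simulate(config, seed, outdir)
    cmd_measure(outdir)
    cmd_efi(outdir, noise=noise)
    return cmd_analyze(outdir)
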
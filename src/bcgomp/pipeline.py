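"""End-to-end two-stage orchestration on synthetic scenes.

Stage I builds the inference model from a full-scalp artifact-only
session (all channels insulated).  Stage II simulates the acquisition
session — the selected channels stay insulated and record artifact only,
the rest record contaminated EEG — then estimates the artifact, recovers
the EEG by both reconstruction routes, runs the optimal-basis-set
baseline, and scores everything against the known ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .core import InferenceModel, Recording, ValidationError, EC
from . import io as bio
from .evaluation import (
    alpha_ec_eo_test,
    ave_nrmse,
    error_map,
)
from .obs import ObsConfig, obs_clean
from .reconstruction import (
    default_mu_grid,
    learn_basis,
    reconstruct_all,
)
from .selection import (
    cross_validate_budget,
    fit_inference,
    lines_pattern,
    omp_select,
    patches_pattern,
    random_pattern,
)
from .simulate import (
    BcgSimConfig,
    EegSimConfig,
    make_schedule,
    perturb_session,
    simulate_bcg,
    simulate_eeg,
)

logger = logging.getLogger("bcgomp")

__all__ = ["PipelineConfig", "Stage1Result", "Stage2Result",
           "run_stage1", "run_stage2", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Config for a full synthetic two-stage run.

    Every random operation receives a seed derived from ``seed``; the
    config round-trips through YAML.
    """

    bcg: BcgSimConfig = field(default_factory=BcgSimConfig)
    eeg: EegSimConfig = field(default_factory=EegSimConfig)
    noise_std: float = 2.0            # acquisition sensor noise, uV
    budget: int = 20
    selection_method: str = "omp"     # omp | lines | patches | random
    reconstruction_method: str = "both"   # subtract | optimize | both
    mu: float | None = None           # None -> validation grid search
    basis_method: str = "pca"
    basis_atoms: int = 40
    segment_len: int = 250
    session_perturb: float = 0.0      # mixing change between stages
    obs: bool = True
    obs_n_pcs: int = 3
    cv_budgets: list | None = None
    cv_folds: int = 4
    val_frac: float = 1.0 / 3.0       # held-out fraction for mu search
    alpha_test: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "bcg" in doc:
            doc["bcg"] = BcgSimConfig(**doc["bcg"])
        if "eeg" in doc:
            doc["eeg"] = EegSimConfig(**doc["eeg"])
        return cls(**doc)


def _seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


@dataclass
class Stage1Result:
    model: InferenceModel
    trace: object
    cv_table: object                    # DataFrame or None
    bcg_rec: Recording
    beats: object
    mixing: np.ndarray
    sources: np.ndarray


def run_stage1(cfg: PipelineConfig, outdir=None) -> Stage1Result:
    """Model building on a simulated full-scalp artifact-only session."""
    s_bcg, s_sel = _seeds(cfg.seed, 2)
    bcg_cfg = replace(cfg.bcg, seed=s_bcg)
    rec, beats, mixing, sources = simulate_bcg(bcg_cfg)
    trace = None
    if cfg.selection_method == "omp":
        model, trace = omp_select(rec, budget=cfg.budget)
    elif cfg.selection_method == "lines":
        subset = lines_pattern(rec.positions,
                               per_group=max(cfg.budget // 4, 1))
        model = fit_inference(rec, subset)
    elif cfg.selection_method == "patches":
        subset = patches_pattern(rec.positions,
                                 per_group=max(cfg.budget // 4, 1))
        model = fit_inference(rec, subset)
    elif cfg.selection_method == "random":
        subset = random_pattern(rec.n_channels, cfg.budget, seed=s_sel)
        model = fit_inference(rec, subset)
    else:
        raise ValidationError(
            f"unknown selection method {cfg.selection_method!r}")
    model.training_meta.update(seed=cfg.seed, fs=rec.fs,
                               training_s=rec.duration,
                               method=cfg.selection_method)
    cv_table = None
    if cfg.cv_budgets:
        cv_table = cross_validate_budget(rec, cfg.cv_budgets,
                                         n_folds=cfg.cv_folds)
    if trace is not None:
        logger.info("selected channels (order): %s",
                    list(model.subset.indices))
        logger.info("residual norms: %s",
                    [round(r, 3) for r in trace.residual_norms])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
        bio.write_model(model, outdir / "model.dat")
        bio.write_recording(rec, outdir / "bcg_training.dat")
        bio.write_beats(beats, outdir / "bcg_training_beats.tsv")
        if cv_table is not None:
            cv_table.to_csv(outdir / "budget_cv.tsv", sep="\t", index=False)
    return Stage1Result(model=model, trace=trace, cv_table=cv_table,
                        bcg_rec=rec, beats=beats, mixing=mixing,
                        sources=sources)


@dataclass
class Stage2Result:
    errors: dict                       # condition -> ave nRMSE (%)
    error_maps: dict
    mu: float | None
    alpha: dict                        # condition -> p-value
    eeg_hat_subtract: Recording | None
    eeg_hat_optimize: Recording | None
    report: dict


def _compose_scene(cfg: PipelineConfig, stage1: Stage1Result):
    """Acquisition session: insulated rows record artifact + noise, the
    rest record artifact + EEG + noise."""
    s_sess, s_eeg, s_eeg_out, s_noise = _seeds(cfg.seed + 1, 4)
    bcg_cfg = replace(cfg.bcg, noise_std=0.0, seed=s_sess)
    bcg_true, beats2, _ = perturb_session(
        stage1.mixing, stage1.sources, cfg.session_perturb, s_sess,
        cfg=bcg_cfg, positions=stage1.bcg_rec.positions)
    schedule = make_schedule(cfg.eeg.T, cfg.eeg.fs,
                             block_s=cfg.eeg.block_s, start=EC)
    eeg_true = simulate_eeg(replace(cfg.eeg, seed=s_eeg), schedule)
    eeg_out = simulate_eeg(replace(cfg.eeg, seed=s_eeg_out), schedule)
    rng = np.random.default_rng(s_noise)
    noise = cfg.noise_std * rng.standard_normal(bcg_true.data.shape) \
        if cfg.noise_std > 0 else np.zeros_like(bcg_true.data)
    ins = stage1.model.subset
    nins = ins.complement()
    Y = bcg_true.data + noise
    Y[nins.row_indices] += eeg_true.data[nins.row_indices]
    return bcg_true, beats2, schedule, eeg_true, eeg_out, Y, ins, nins


def run_stage2(cfg: PipelineConfig, stage1: Stage1Result,
               outdir=None) -> Stage2Result:
    """Acquisition, artifact inference, reconstruction and evaluation."""
    (bcg_true, beats2, schedule, eeg_true, eeg_out,
     Y, ins, nins) = _compose_scene(cfg, stage1)
    fs = cfg.bcg.fs
    X_ins = Y[ins.row_indices]                        # artifact-only + noise
    Y_nins = Recording(Y[nins.row_indices], fs=fs,
                       labels=[str(i) for i in nins.indices])
    truth_nins = Recording(eeg_true.data[nins.row_indices], fs=fs,
                           labels=list(Y_nins.labels))
    bcg_hat = Recording(stage1.model.W @ X_ins, fs=fs,
                        labels=list(Y_nins.labels))

    # held-out split: mu tuned on the first val_frac, scored on the rest
    T = Y_nins.n_samples
    n_val = int(T * cfg.val_frac)
    ev = slice(n_val, T)

    def score(rec: Recording) -> float:
        return ave_nrmse(truth_nins.data[:, ev], rec.data[:, ev])

    errors: dict[str, float] = {"contaminated": score(Y_nins)}
    maps = {"contaminated": error_map(truth_nins, Y_nins)}

    sub = reconstruct_all(Y_nins, bcg_hat, method="subtract")
    errors["omp_subtract"] = score(sub)
    maps["omp_subtract"] = error_map(truth_nins, sub)

    opt = None
    mu_used = None
    if cfg.reconstruction_method in ("optimize", "both"):
        basis = learn_basis(eeg_out, L=cfg.segment_len, m=cfg.basis_atoms,
                            method=cfg.basis_method)
        if cfg.mu is not None:
            mu_used = float(cfg.mu)
        else:
            grid = default_mu_grid(sub.data[:, :n_val], basis.m, basis.L)
            best = None
            for mu in grid:
                cand = reconstruct_all(
                    Recording(Y_nins.data[:, :n_val], fs=fs),
                    Recording(bcg_hat.data[:, :n_val], fs=fs),
                    basis=basis, method="optimize", mu=float(mu))
                err = ave_nrmse(truth_nins.data[:, :n_val], cand.data)
                if best is None or err < best[0]:
                    best = (err, float(mu))
            mu_used = best[1]
        opt = reconstruct_all(Y_nins, bcg_hat, basis=basis,
                              method="optimize", mu=mu_used)
        errors["omp_optimize"] = score(opt)
        maps["omp_optimize"] = error_map(truth_nins, opt)

    if cfg.obs:
        cleaned = obs_clean(Y_nins, beats2, ObsConfig(n_pcs=cfg.obs_n_pcs))
        errors["obs"] = score(cleaned)
        maps["obs"] = error_map(truth_nins, cleaned)

    alpha: dict[str, float] = {}
    if cfg.alpha_test:
        # most posterior non-insulated channel carries the alpha rhythm
        pos = eeg_true.positions[nins.row_indices]
        ch_row = int(np.argmin(pos[:, 1]))
        try:
            alpha["contaminated"] = alpha_ec_eo_test(
                Y_nins, schedule, ch_row + 1).p_value
            alpha["omp_subtract"] = alpha_ec_eo_test(
                sub, schedule, ch_row + 1).p_value
            alpha["clean_truth"] = alpha_ec_eo_test(
                truth_nins, schedule, ch_row + 1).p_value
        except ValidationError as exc:     # recording too short
            logger.warning("alpha test skipped: %s", exc)

    report = {
        "errors_pct": {k: round(v, 2) for k, v in errors.items()},
        "alpha_p_values": alpha,
        "mu": mu_used,
        "subset": list(ins.indices),
        "n_channels_evaluated": len(nins),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        bio.write_recording(sub, outdir / "eeg_subtract.dat")
        if opt is not None:
            bio.write_recording(opt, outdir / "eeg_optimize.dat")
        for name, m in maps.items():
            m.to_frame().to_csv(outdir / f"errmap_{name}.tsv", sep="\t",
                                index=False)
    return Stage2Result(errors=errors, error_maps=maps, mu=mu_used,
                        alpha=alpha, eeg_hat_subtract=sub,
                        eeg_hat_optimize=opt, report=report)


def run_pipeline(cfg: PipelineConfig, outdir=None):
    """Stage I + Stage II; returns (Stage1Result, Stage2Result)."""
    out1 = Path(outdir) / "stage1" if outdir is not None else None
    out2 = Path(outdir) / "stage2" if outdir is not None else None
    s1 = run_stage1(cfg, outdir=out1)
    s2 = run_stage2(cfg, s1, outdir=out2)
    return s1, s2
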
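"""End-to-end orchestration: simulate → pretrain → meta-train → adapt → evaluate.

The experiment protocol is leave-subjects-out: a synthetic cohort is split into
training subjects (pretraining + meta-training) and held-out subjects
(few-shot adaptation targets).  A ``pretrain_fraction`` flag subsamples the
training subjects' clips to emulate small/middle/large-scale pretraining.
Every stage derives its randomness from the run seed, so a rerun with the same
config reproduces reports exactly on one device.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ClipArrays, prepare_clips
from .encoders import ImageEncoderConfig
from .errors import ConfigurationError
from .evaluation import evaluate_model, relative_reduction
from .fusion import PoseModel, PoseModelConfig, PretrainConfig
from .meta import (MetaConfig, MetaLearner, TaskDefinition, meta_adapt,
                   meta_train, sample_episode, task_loss_mask)
from .synthetic import CohortDataset, GeneratorConfig, make_cohort


def desk_model_config(modalities=("image", "emg", "vio"), use_ks: bool = True,
                      **overrides) -> PoseModelConfig:
    """The reduced architecture used for CPU-scale experiments and tests."""
    kw = dict(
        modalities=tuple(modalities),
        use_ks=use_ks,
        shared_dim=32,
        branch_widths=(16, 16, 16),
        decoder_hidden=48,
        n_out=25,
        dropout=0.1,
        image=ImageEncoderConfig(frames=2, spatial_stride=3,
                                 widths=(8, 16, 32, 64), reduction=4,
                                 spatial_kernel=3),
        emg_kwargs=dict(d_model=32, n_heads=2, n_layers=1, d_ff=64),
        vio_kwargs=dict(d_model=32, n_heads=2, n_layers=1, d_ff=64),
        input_hw=64,
    )
    kw.update(overrides)
    return PoseModelConfig(**kw)


@dataclass
class RunConfig:
    n_subjects: int = 8
    trials_per_speed: int = 1
    held_out_subjects: int = 2
    pretrain_fraction: float = 1.0        # 0.5 / 0.75 / 1.0 scale models
    task_axis: str = "subject"
    shots: tuple = (1, 5)
    adapt_repeats: int = 2                # episodes per held-out task level
    q_query: int = 8
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: PoseModelConfig = field(default_factory=desk_model_config)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    held_out_subject_ids: tuple | None = None   # explicit override
    out_dir: str | None = None
    write_cohort: bool = False

    def resolved_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(json.loads(json.dumps(d, default=list)), sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("write_cohort", None)
        text = yaml.safe_dump(json.loads(json.dumps(d, default=list)), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def split_subjects(subject_ids, held_out: int, explicit=None) -> tuple:
    """Deterministic leave-subjects-out split; the last ``held_out`` ids (in
    sorted order) are the adaptation targets unless given explicitly."""
    ids = sorted(subject_ids)
    if explicit is not None:
        held = sorted(explicit)
        if any(h not in ids for h in held):
            raise ConfigurationError(f"held-out ids {held} not all in cohort")
        train = [s for s in ids if s not in held]
    else:
        if held_out >= len(ids):
            raise ConfigurationError("held_out_subjects must leave >= 1 training subject")
        held = ids[-held_out:]
        train = ids[:-held_out]
    if set(train) & set(held):
        raise ConfigurationError(
            f"adaptation targets {sorted(set(train) & set(held))} appear in the "
            "pretraining set")
    return train, held


def subsample_fraction(data: ClipArrays, fraction: float, seed: int) -> ClipArrays:
    if not 0 < fraction <= 1:
        raise ConfigurationError("pretrain_fraction must lie in (0, 1]")
    if fraction == 1.0:
        return data
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(data))))
    idx = np.sort(rng.choice(len(data), size=n, replace=False))
    return data.subset(idx)


def few_shot_table(pretrained: PoseModel, learner: MetaLearner,
                   data: ClipArrays, tasks: list, shots, repeats: int,
                   q_query: int, seed: int) -> pd.DataFrame:
    """Few-shot RMSE per task level and shot count, with shared query sets.

    For each task and repeat, one episode with K = max(shots ∪ {1}) support
    clips and ``q_query`` queries is drawn; the s-shot model adapts on the
    first s support clips, and shot 0 is the unadapted pretrained model — all
    evaluated on the same queries.
    """
    shots = sorted(set(int(s) for s in shots) | {0})
    k_max = max(max(shots), 1)
    rows = []
    for t_i, task in enumerate(tasks):
        for r in range(repeats):
            ep_seed = _derive_seed(seed, f"episode:{t_i}:{r}")
            ep = sample_episode(data, task, k_shot=k_max, q_query=q_query,
                                seed=ep_seed)
            qmask = ep.query_loss_mask
            for s in shots:
                if s == 0:
                    model = pretrained
                else:
                    sup = ep.support.subset(np.arange(s))
                    smask = None
                    m = task_loss_mask(ep.support, task)
                    if m is not None:
                        smask = m[:s]
                    model = meta_adapt(learner, sup, loss_mask=smask)
                pred = model.predict(ep.query.arrays)
                sq = (pred - ep.query.targets) ** 2
                if qmask is not None:
                    sq = sq[qmask]
                rows.append(dict(task_axis=task.axis, task_level=str(task.level),
                                 repeat=r, shots=s,
                                 rmse_deg=float(np.sqrt(sq.mean())),
                                 n_query=len(ep.query)))
    return pd.DataFrame(rows)


def _heldout_tasks(axis: str, held_ids) -> list:
    if axis == "subject":
        return [TaskDefinition("subject", int(s)) for s in held_ids]
    if axis == "speed":
        return [TaskDefinition("speed", lvl) for lvl in ("slow", "moderate", "fast")]
    if axis == "phase":
        return [TaskDefinition("phase", lvl) for lvl in ("stance", "swing")]
    raise ConfigurationError(f"unknown task axis {axis!r}")


def run_experiment(config: RunConfig) -> dict:
    """Execute the three-stage protocol; returns (and optionally writes) the
    results: per-shot RMSE table, summary, logs, and checkpoint lineage."""
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.resolved_yaml())

    cohort_seed = _derive_seed(config.seed, "cohort")
    cohort_path = (out / "cohort.h5") if (out and config.write_cohort) else None
    dataset = make_cohort(config.n_subjects, config.trials_per_speed,
                          seed=cohort_seed, config=config.generator,
                          path=cohort_path)
    train_ids, held_ids = split_subjects(dataset.subject_ids,
                                         config.held_out_subjects,
                                         config.held_out_subject_ids)

    clips = dataset.clips()
    all_data = prepare_clips(clips, config.model)
    train_data = all_data.subset(np.flatnonzero(np.isin(all_data.subject_ids, train_ids)))
    held_data = all_data.subset(np.flatnonzero(np.isin(all_data.subject_ids, held_ids)))
    # the scale flag shrinks the pretraining data only (small/middle/large
    # pretrained models); meta-training episodes draw from the full pool
    pretrain_data = subsample_fraction(train_data, config.pretrain_fraction,
                                       _derive_seed(config.seed, "fraction"))

    # stage 1: pretraining
    pre_cfg = replace(config.pretrain, seed=_derive_seed(config.seed, "pretrain"))
    model, pre_log = _pretrain_on(pretrain_data, config.model, pre_cfg)

    # stage 2: meta-transfer on the training pool; episodes use the same shot
    # counts as the evaluation protocol (episodic training matches testing)
    eval_shots = tuple(int(s) for s in config.shots if int(s) > 0)
    meta_cfg = replace(config.meta, seed=_derive_seed(config.seed, "meta"),
                       k_shot=eval_shots or config.meta.k_shot)
    train_tasks = ([TaskDefinition("subject", int(s)) for s in train_ids]
                   if config.task_axis == "subject"
                   else _heldout_tasks(config.task_axis, train_ids))
    learner, meta_log = meta_train(model, train_data, train_tasks, meta_cfg)

    # stage 3: meta-adaptation on held-out tasks
    tasks = _heldout_tasks(config.task_axis, held_ids)
    table = few_shot_table(model, learner, held_data, tasks, config.shots,
                           config.adapt_repeats, config.q_query,
                           _derive_seed(config.seed, "adapt"))
    by_shot = table.groupby("shots")["rmse_deg"].mean().to_dict()
    max_shot = max(int(s) for s in config.shots)
    summary = {
        "rmse_by_shot_deg": {int(k): float(v) for k, v in by_shot.items()},
        "relative_reduction_max_shot": relative_reduction(
            by_shot[0], by_shot[max_shot]),
        "train_subjects": [int(s) for s in train_ids],
        "held_out_subjects": [int(s) for s in held_ids],
        "pretrain_fraction": config.pretrain_fraction,
        "config_hash": config.config_hash(),
        "lineage": {
            "config": config.config_hash(),
            "pretrained": _state_hash(model),
            "meta_learner": _params_hash(learner.mod_init.parameters()
                                         + (learner.decoder_init or [])),
        },
    }
    report = evaluate_model(model, held_data, model_id="pretrained",
                            task_axis=config.task_axis, shots=0,
                            seeds=[config.seed])
    results = dict(summary=summary, few_shot_table=table, pretrain_log=pre_log,
                   meta_log=meta_log, pretrained_report=report,
                   model=model, learner=learner, dataset=dataset)
    if out is not None:
        table.to_csv(out / "few_shot_rmse.csv", index=False)
        pre_log.to_csv(out / "pretrain_log.csv", index=False)
        meta_log.to_csv(out / "meta_log.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "pretrained_report.json").write_text(report.to_json())
        from .fusion import save_pose_model
        save_pose_model(model, out / "pretrained.npz",
                        extra={"config_hash": config.config_hash()})
    return results


def _pretrain_on(data: ClipArrays, model_cfg: PoseModelConfig,
                 pre_cfg: PretrainConfig):
    """Pretrain directly on prepared clip arrays (val split inside)."""
    from . import fusion

    rng = np.random.default_rng(pre_cfg.seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(pre_cfg.val_fraction * len(data)))) \
        if pre_cfg.val_fraction > 0 else 0
    val = data.subset(order[:n_val]) if n_val else None
    tr = data.subset(order[n_val:]) if n_val else data
    return fusion.pretrain_arrays(tr, model_cfg, pre_cfg, val_data=val)


def _state_hash(model: PoseModel) -> str:
    h = hashlib.sha256()
    for k, v in sorted(model.state_dict().items()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(v).tobytes())
    return h.hexdigest()[:16]


def _params_hash(params) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()[:16]


# -------------------------------------------------------------------- ablation
@dataclass
class AblationConfig:
    arms: tuple = (("all", ("image", "emg", "vio"), True),
                   ("nKS", ("image", "emg", "vio"), False))
    n_subjects: int = 5
    trials_per_speed: int = 1
    held_out_subjects: int = 1
    shots: tuple = (1, 5)
    adapt_repeats: int = 2
    q_query: int = 8
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)


def run_ablation_arms(config: AblationConfig) -> pd.DataFrame:
    """Train/evaluate each arm with shared cohort, split, seeds and episodes."""
    rows = []
    for name, modalities, use_ks in config.arms:
        if tuple(modalities) == ("vio",):
            raise ConfigurationError(
                "VIO-only arm rejected: VIO lacks spatial context")
        run_cfg = RunConfig(
            n_subjects=config.n_subjects,
            trials_per_speed=config.trials_per_speed,
            held_out_subjects=config.held_out_subjects,
            shots=config.shots,
            adapt_repeats=config.adapt_repeats,
            q_query=config.q_query,
            seed=config.seed,
            generator=config.generator,
            model=desk_model_config(modalities=tuple(modalities), use_ks=use_ks),
            pretrain=config.pretrain,
            meta=config.meta,
        )
        res = run_experiment(run_cfg)
        row = {"arm": name, "modalities": "+".join(modalities), "use_ks": use_ks}
        for s, v in res["summary"]["rmse_by_shot_deg"].items():
            label = "pretrained" if s == 0 else f"{s}-shot"
            row[f"rmse_{label}_deg"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ validation
def validate_cohort(path) -> dict:
    """Check the stream invariants of a stored cohort; returns a report with
    per-check pass/fail and details."""
    checks = {}

    def add(name, ok, detail=""):
        checks[name] = {"ok": bool(ok), "detail": detail}

    try:
        ds = CohortDataset.open(path)
    except Exception as exc:  # corrupt / empty file
        raise IOError(f"cannot open cohort file {path}: {exc}") from exc

    expected = {"image": ds.config.image_rate, "emg": ds.config.emg_rate,
                "vio": ds.config.vio_rate, "angles": ds.config.angle_rate}
    for i, meta in enumerate(ds.trial_metas):
        trial = ds.load_trial(i)
        tag = f"s{meta.subject_id}t{meta.trial_index}"
        for mod, rate in expected.items():
            st = trial.streams[mod]
            want = round(rate * meta.duration_s)
            add(f"{tag}:{mod}:count", st.n_samples == want,
                f"{st.n_samples} vs {want}")
        add(f"{tag}:emg:dim", trial.streams["emg"].samples.shape[1] == 6)
        add(f"{tag}:angles:dim", trial.streams["angles"].samples.shape[1] == 6)
        add(f"{tag}:vio:dim", trial.streams["vio"].samples.shape[1] >= 7)
        q = trial.streams["vio"].samples[:, 3:7]
        qerr = float(np.abs(np.linalg.norm(q, axis=1) - 1.0).max())
        add(f"{tag}:vio:quat_norm", qerr < 1e-6, f"max dev {qerr:.2e}")
        img = trial.streams["image"].samples
        add(f"{tag}:image:shape",
            img.ndim == 4 and img.shape[1] == img.shape[2] == ds.config.image_size
            and img.shape[3] == ds.config.image_channels, str(img.shape))
        # phase mask: one stance and one swing interval per gait cycle
        mask = trial.phase_stance
        flips = int(np.count_nonzero(mask[1:] != mask[:-1]))
        n_cycles = meta.stride_freq * meta.duration_s
        add(f"{tag}:phase:structure", abs(flips - 2 * n_cycles) <= 2,
            f"{flips} transitions vs {2 * n_cycles:.1f} expected")
        frac = float(mask.mean())
        lo, hi = ds.config.stance_band
        add(f"{tag}:phase:stance_fraction", lo - 0.02 <= frac <= hi + 0.02,
            f"{frac:.3f}")
    ok = all(c["ok"] for c in checks.values())
    return {"ok": ok, "n_checks": len(checks),
            "failed": {k: v for k, v in checks.items() if not v["ok"]}}
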
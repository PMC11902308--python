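"""RMSE metrics, model comparison reports, and the ablation harness.

The headline accuracy metric is the pooled RMSE in degrees over all joints and
decoded samples (so pooled RMSE² equals the pose MSE on the same flattening);
per-joint, per-phase and per-speed breakdowns are reported alongside.
Relative reduction between two models is (before − after) / before.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data import ClipArrays
from .errors import DomainError


def rmse_degrees(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Overall and per-joint RMSE (degrees).

    ``pred``/``truth``: (..., 6) arrays over any sample layout.  Per-joint
    RMSE_j = sqrt(mean over samples of squared residual); overall pools all
    joints and samples.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise DomainError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.shape[-1] != 6:
        raise DomainError("trailing axis must hold the 6 joint angles")
    sq = (pred - truth) ** 2
    flat = sq.reshape(-1, 6)
    return {
        "overall": float(np.sqrt(flat.mean())),
        "per_joint": np.sqrt(flat.mean(axis=0)),
    }


@dataclass
class EvaluationReport:
    model_id: str
    task_axis: str
    shots: int
    overall_rmse_deg: float
    per_joint_rmse_deg: list
    per_phase_rmse_deg: dict
    per_speed_rmse_deg: dict
    n_clips: int
    n_samples: int
    seeds: list
    sq_residual_sum: float        # pooled sum of squared residuals
    phase_counts: dict            # phase -> flattened residual count

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def evaluate_model(model_like, data: ClipArrays, model_id: str = "model",
                   task_axis: str = "subject", shots: int = 0,
                   seeds: list | None = None) -> EvaluationReport:
    """Predict on prepared clips and assemble the full RMSE breakdown."""
    pred = model_like.predict(data.arrays)
    truth = data.targets
    base = rmse_degrees(pred, truth)
    sq = (pred - truth) ** 2
    per_phase, counts = {}, {}
    for phase, mask in (("stance", data.stance_mask), ("swing", ~data.stance_mask)):
        sel = sq[mask]                           # (n_sel, 6)
        per_phase[phase] = float(np.sqrt(sel.mean())) if sel.size else float("nan")
        counts[phase] = int(sel.size)
    per_speed = {}
    for spd in np.unique(data.speed_classes):
        sel = sq[data.speed_classes == spd]
        per_speed[str(spd)] = float(np.sqrt(sel.mean()))
    return EvaluationReport(
        model_id=model_id,
        task_axis=task_axis,
        shots=shots,
        overall_rmse_deg=base["overall"],
        per_joint_rmse_deg=[float(v) for v in base["per_joint"]],
        per_phase_rmse_deg=per_phase,
        per_speed_rmse_deg=per_speed,
        n_clips=len(data),
        n_samples=int(np.prod(truth.shape[:-1])),
        seeds=list(seeds or []),
        sq_residual_sum=float(sq.sum()),
        phase_counts=counts,
    )


def relative_reduction(before: float, after: float) -> float:
    """(before − after) / before — the error-reduction convention used in the
    few-shot comparisons."""
    return (before - after) / before


def compare_models(models: dict, episodes: list) -> tuple:
    """Evaluate several models on the shared query sets of a list of episodes.

    Returns (per-model-per-episode DataFrame, pairwise relative-reduction
    DataFrame on the pooled query RMSE).
    """
    if not episodes:
        raise DomainError("no episodes to compare on")
    keys0 = [tuple(ep.query.clip_keys) for ep in episodes]
    rows = []
    pooled = {}
    for name, model in models.items():
        sq_sum, n = 0.0, 0
        for e_i, ep in enumerate(episodes):
            pred = model.predict(ep.query.arrays)
            sq = (pred - ep.query.targets) ** 2
            rows.append(dict(model=name, episode=e_i,
                             rmse_deg=float(np.sqrt(sq.mean())),
                             n_clips=len(ep.query)))
            sq_sum += sq.sum()
            n += sq.size
        pooled[name] = float(np.sqrt(sq_sum / n))
    red_rows = []
    names = list(models)
    for a in names:
        for b in names:
            red_rows.append(dict(
                before=a, after=b,
                rmse_before=pooled[a], rmse_after=pooled[b],
                relative_reduction=relative_reduction(pooled[a], pooled[b]),
            ))
    return pd.DataFrame(rows), pd.DataFrame(red_rows)


def run_ablation(config) -> pd.DataFrame:
    """Train and evaluate every requested arm (modality subsets and/or KS vs
    nKS) with shared seeds, cohort, splits and episodes.

    ``config`` is an ``AblationConfig`` from :mod:`metagait.pipeline`; returns a
    tidy table with one row per arm and pretrained / k-shot RMSE columns.
    """
    from .pipeline import run_ablation_arms

    return run_ablation_arms(config)
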
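"""Clip preprocessing: turn MultimodalClips into dense training arrays.

The decoder predicts the 6 joint angles at ``n_out`` uniformly spaced time
points of each 10-s clip, so targets (and the stance/swing mask used by
phase-restricted tasks) are the ground-truth trajectory sampled at those
points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import preprocess_image, preprocess_sequence, default_emg_config, default_vio_config
from .errors import DomainError


@dataclass
class ClipArrays:
    """Preprocessed clips ready for the network, with labels and targets."""

    arrays: dict                 # modality -> stacked array (N leading axis)
    targets: np.ndarray          # (N, n_out, 6) degrees
    stance_mask: np.ndarray      # (N, n_out) bool, True in stance
    subject_ids: np.ndarray      # (N,)
    speed_classes: np.ndarray    # (N,) str
    clip_keys: list              # (subject_id, trial_index, clip_index) tuples

    def __len__(self):
        return len(self.targets)

    def subset(self, idx) -> "ClipArrays":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.intp)
        return ClipArrays(
            arrays={m: v[idx] for m, v in self.arrays.items()},
            targets=self.targets[idx],
            stance_mask=self.stance_mask[idx],
            subject_ids=self.subject_ids[idx],
            speed_classes=self.speed_classes[idx],
            clip_keys=[self.clip_keys[i] for i in idx],
        )


def target_indices(n_samples: int, n_out: int) -> np.ndarray:
    return np.round(np.linspace(0, n_samples - 1, n_out)).astype(int)


def prepare_clips(clips, model_config) -> ClipArrays:
    """Preprocess a list of MultimodalClips for a given PoseModelConfig."""
    if not clips:
        raise DomainError("no clips to prepare")
    cfg = model_config
    mods = cfg.modalities
    emg_cfg = default_emg_config(**cfg.emg_kwargs)
    vio_cfg = default_vio_config(**cfg.vio_kwargs)
    arrays = {m: [] for m in mods}
    targets, masks, sids, spds, keys = [], [], [], [], []
    for clip in clips:
        if "image" in mods:
            arrays["image"].append(preprocess_image(
                clip.streams["image"].samples, cfg.image.frames,
                cfg.image.spatial_stride))
        if "emg" in mods:
            arrays["emg"].append(preprocess_sequence(
                clip.streams["emg"].samples, emg_cfg))
        if "vio" in mods:
            arrays["vio"].append(preprocess_sequence(
                clip.streams["vio"].samples, vio_cfg))
        idx = target_indices(clip.angles.shape[0], cfg.n_out)
        targets.append(clip.angles[idx])
        masks.append(clip.phase_stance[idx])
        sids.append(clip.subject_id)
        spds.append(clip.speed_class)
        keys.append((clip.subject_id, clip.trial_index, clip.clip_index))
    return ClipArrays(
        arrays={m: np.stack(v).astype(np.float32) for m, v in arrays.items()},
        targets=np.stack(targets),
        stance_mask=np.stack(masks),
        subject_ids=np.asarray(sids),
        speed_classes=np.asarray(spds),
        clip_keys=keys,
    )
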
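"""Motor-cortex scouts: 9 left/right pairs of 20-vertex cortical ROIs.

Each scout is the cortical patch under one of 18 sensorimotor electrodes
(FC5...CP1 on the left, FC6...CP2 on the right).  Its aggregated time series
acts as a virtual electrode; the left and right series of each pair are
stacked into the 1280 x 9 matrix consumed by the dual-branch classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .headmodel import SensorArray, SourceSpace
from .preprocess import EpochSet

__all__ = [
    "MOTOR_PAIR_NAMES",
    "Scout",
    "ScoutPairing",
    "define_motor_scouts",
    "extract_scout_series",
    "assemble_input",
    "split_branches",
    "scouts_to_json",
    "scouts_from_json",
    "ScoutAssembler",
]

#: The nine left/right electrode pairs, fixed column order of the assembled
#: input: FC row, C row, CP row, lateral to medial.
MOTOR_PAIR_NAMES: tuple[tuple[str, str], ...] = (
    ("FC5", "FC6"), ("FC3", "FC4"), ("FC1", "FC2"),
    ("C5", "C6"), ("C3", "C4"), ("C1", "C2"),
    ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
)

N_VERTICES_PER_SCOUT = 20


@dataclass
class Scout:
    """A cortical ROI: 20 source vertices under one electrode."""

    name: str
    hemisphere: str  # "left" | "right"
    vertex_indices: np.ndarray
    orientation_signs: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=int)
        self.orientation_signs = np.asarray(self.orientation_signs, dtype=int)
        if self.vertex_indices.shape != (N_VERTICES_PER_SCOUT,):
            raise ValueError(
                f"scout {self.name}: expected {N_VERTICES_PER_SCOUT} "
                f"vertices, got {self.vertex_indices.shape}"
            )
        if self.orientation_signs.shape != self.vertex_indices.shape:
            raise ValueError("one orientation sign per vertex required")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass
class ScoutPairing:
    """Indices of the left/right scouts for each of the 9 pair columns."""

    names: tuple[tuple[str, str], ...]
    left_indices: np.ndarray
    right_indices: np.ndarray

    def __post_init__(self) -> None:
        self.left_indices = np.asarray(self.left_indices, dtype=int)
        self.right_indices = np.asarray(self.right_indices, dtype=int)
        if not (len(self.names) == len(self.left_indices)
                == len(self.right_indices) == len(MOTOR_PAIR_NAMES)):
            raise ValueError("pairing must cover the 9 fixed pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.names)


def define_motor_scouts(
    source_space: SourceSpace,
    montage: SensorArray,
) -> tuple[list[Scout], ScoutPairing]:
    """Build the 18 scouts by projecting electrodes onto the cortex.

    Each of the 18 electrode positions is projected radially onto the source
    sphere; the 20 nearest vertices (Euclidean) form the scout.  Scouts are
    kept disjoint: vertices are claimed greedily in the fixed pair order,
    left scout before right within a pair.  Returned scouts are ordered as
    the 9 left scouts followed by the 9 right scouts, matching the pairing.
    """
    n_src = len(source_space)
    needed = 2 * len(MOTOR_PAIR_NAMES) * N_VERTICES_PER_SCOUT
    if n_src < needed:
        raise ValueError(
            f"source space has {n_src} vertices; at least {needed} are "
            "needed for 18 disjoint 20-vertex scouts"
        )
    src_radius = float(np.median(np.linalg.norm(source_space.positions, axis=1)))
    taken = np.zeros(n_src, dtype=bool)
    by_name: dict[str, Scout] = {}
    for left_name, right_name in MOTOR_PAIR_NAMES:
        for name, hemi in ((left_name, "left"), (right_name, "right")):
            sensor = montage.positions[montage.index(name)]
            target = sensor / np.linalg.norm(sensor) * src_radius
            d = np.linalg.norm(source_space.positions - target, axis=1)
            d[taken] = np.inf
            idx = np.argsort(d)[:N_VERTICES_PER_SCOUT]
            taken[idx] = True
            mean_ori = source_space.orientations[idx].mean(axis=0)
            signs = np.sign(source_space.orientations[idx] @ mean_ori)
            signs[signs == 0] = 1
            by_name[name] = Scout(name=name, hemisphere=hemi,
                                  vertex_indices=idx,
                                  orientation_signs=signs.astype(int))
    scouts = ([by_name[l] for l, _ in MOTOR_PAIR_NAMES]
              + [by_name[r] for _, r in MOTOR_PAIR_NAMES])
    pairing = ScoutPairing(
        names=MOTOR_PAIR_NAMES,
        left_indices=np.arange(9),
        right_indices=np.arange(9, 18),
    )
    return scouts, pairing


def _sign_aligned_mean(vertex_series: np.ndarray) -> np.ndarray:
    """Mean over vertices after aligning polarities.

    ``vertex_series`` is (n_vertices, n_samples).  Signs are chosen so each
    vertex series correlates non-negatively with the first principal
    direction of the patch.  The overall polarity is canonicalised so a
    majority of vertices keep their sign; on an exact tie the first vertex's
    sign is forced positive.
    """
    x = vertex_series
    # first right-singular vector = dominant temporal pattern of the patch
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    u = vt[0]
    signs = np.sign(x @ u)
    signs[signs == 0] = 1.0
    total = signs.sum()
    if total < 0 or (total == 0 and signs[0] < 0):
        signs = -signs
    return (signs[:, None] * x).mean(axis=0)


def extract_scout_series(
    source_epochs: EpochSet | np.ndarray,
    scouts: list[Scout],
) -> np.ndarray:
    """Aggregate source epochs into scout series: trials x n_scouts x samples.

    Per scout, the sign-aligned mean of its vertex series.  The alignment is
    computed once per scout from all trials concatenated, so a scout keeps a
    single polarity across the dataset.
    """
    data = source_epochs.epochs if isinstance(source_epochs, EpochSet) else np.asarray(source_epochs)
    if data.ndim != 3:
        raise ValueError("source epochs must be trials x sources x samples")
    n_trials, n_src, n_samp = data.shape
    out = np.empty((n_trials, len(scouts), n_samp))
    for k, scout in enumerate(scouts):
        if scout.vertex_indices.max() >= n_src:
            raise IndexError(
                f"scout {scout.name} refers to vertex "
                f"{int(scout.vertex_indices.max())} but only {n_src} sources "
                "are present"
            )
        patch = data[:, scout.vertex_indices, :]           # (trials, 20, T)
        stacked = patch.transpose(1, 0, 2).reshape(len(scout.vertex_indices), -1)
        aligned = _sign_aligned_mean(stacked)
        out[:, k, :] = aligned.reshape(n_trials, n_samp)
    return out


def assemble_input(
    scout_series: np.ndarray,
    pairing: ScoutPairing,
) -> np.ndarray:
    """Stack paired scout series into the network input.

    ``scout_series`` is trials x 18 x T.  Column j of the output
    (trials x 2T x 9) is the left series of pair j followed by the right
    series, so a 2-way reshape recovers the two T x 9 branch arrays.
    """
    x = np.asarray(scout_series)
    if x.ndim != 3 or x.shape[1] < 2 * pairing.n_pairs:
        raise ValueError(
            f"scout series must be trials x 18 x samples, got {x.shape}"
        )
    left = x[:, pairing.left_indices, :]    # (trials, 9, T)
    right = x[:, pairing.right_indices, :]
    stacked = np.concatenate([left, right], axis=2)  # (trials, 9, 2T)
    return stacked.transpose(0, 2, 1)                # (trials, 2T, 9)


def split_branches(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`assemble_input` on the row axis.

    Accepts one trial (2T x 9) or a batch (trials x 2T x 9); returns the
    left and right T x 9 branch arrays.
    """
    x = np.asarray(x)
    rows = x.shape[-2]
    if x.ndim not in (2, 3) or rows % 2 != 0:
        raise ValueError(f"assembled input must have an even row count, got shape {x.shape}")
    half = rows // 2
    return x[..., :half, :], x[..., half:, :]


def scouts_to_json(scouts: list[Scout], pairing: ScoutPairing, path) -> None:
    payload = {
        "pairs": [list(p) for p in pairing.names],
        "scouts": [
            {
                "name": s.name,
                "hemisphere": s.hemisphere,
                "vertex_indices": s.vertex_indices.tolist(),
                "orientation_signs": s.orientation_signs.tolist(),
            }
            for s in scouts
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def scouts_from_json(path) -> tuple[list[Scout], ScoutPairing]:
    payload = json.loads(Path(path).read_text())
    scouts = [
        Scout(name=d["name"], hemisphere=d["hemisphere"],
              vertex_indices=np.array(d["vertex_indices"]),
              orientation_signs=np.array(d["orientation_signs"]))
        for d in payload["scouts"]
    ]
    names = tuple(tuple(p) for p in payload["pairs"])
    order = {s.name: i for i, s in enumerate(scouts)}
    pairing = ScoutPairing(
        names=names,
        left_indices=np.array([order[l] for l, _ in names]),
        right_indices=np.array([order[r] for _, r in names]),
    )
    return scouts, pairing


class ScoutAssembler(TransformerMixin, BaseEstimator):
    """Transformer: source epochs -> assembled 1280 x 9 network inputs."""

    def __init__(self, scouts=None, pairing=None):
        self.scouts = scouts
        self.pairing = pairing

    def fit(self, X, y=None):
        if self.scouts is None or self.pairing is None:
            raise ValueError("ScoutAssembler needs scouts and pairing")
        self.n_scouts_ = len(self.scouts)
        return self

    def transform(self, X):
        series = extract_scout_series(X, self.scouts)
        return assemble_input(series, self.pairing)
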
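"""Trial and skeleton data structures, file IO, preprocessing and fold construction.

A trial is one timed-up-and-go-like recording: N reflective markers
tracked in 3-D (x anterior/posterior, y lateral, z vertical, in mm) at
120 Hz, labeled at the session level with medication state (OFF/ON),
freezing-of-gait score (0-4) and the MDS-UPDRS-III motor total with the
FOG item removed (0-120).  Trials are hip-centered, z-normalized per
channel, cut into fixed-length analysis windows, and split into grouped
train/validation/test folds that never separate windows of the same
trial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

MED_STATES = ("OFF", "ON")
GROUPS = ("PD-FOG", "PD-NoFOG", "PP-FOG")


# ---------------------------------------------------------------------- #
# skeleton
# ---------------------------------------------------------------------- #
@dataclass
class SkeletonGraph:
    """Marker graph: nodes are kinematic markers, edges are skeletal segments."""

    marker_names: list[str]
    edges: list[tuple[int, int]]
    root: str

    def __post_init__(self):
        n = len(self.marker_names)
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references invalid marker index")
        g = nx.Graph(self.edges)
        g.add_nodes_from(range(n))
        if not nx.is_connected(g):
            raise ValueError("skeleton graph is not connected")
        if self.root not in self.marker_names:
            raise ValueError(f"root marker {self.root!r} not in marker list")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def root_index(self) -> int:
        return self.marker_names.index(self.root)

    def index(self, name: str) -> int:
        return self.marker_names.index(name)

    def hop_distances(self) -> np.ndarray:
        """Graph distance of every marker from the root."""
        g = nx.Graph(self.edges)
        g.add_nodes_from(range(self.n_markers))
        d = nx.single_source_shortest_path_length(g, self.root_index)
        return np.array([d[i] for i in range(self.n_markers)])

    def subset_adjacencies(self) -> np.ndarray:
        """Spatial-configuration partition into Kv=3 binary adjacency subsets.

        Subset 0: self-loops plus neighbours at equal root distance;
        subset 1: centripetal neighbours (closer to the root);
        subset 2: centrifugal neighbours (farther from the root).
        The union of nonzero entries equals self-loops plus the skeletal
        edges.
        """
        n = self.n_markers
        dist = self.hop_distances()
        A = np.zeros((3, n, n))
        A[0] += np.eye(n)
        for i, j in self.edges:
            for a, b in ((i, j), (j, i)):
                if dist[b] < dist[a]:
                    A[1, a, b] = 1.0  # neighbour b is nearer the root
                elif dist[b] > dist[a]:
                    A[2, a, b] = 1.0
                else:
                    A[0, a, b] = 1.0
        return A

    @classmethod
    def from_json(cls, path) -> "SkeletonGraph":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker_names=list(d["markers"]),
            edges=[tuple(e) for e in d["edges"]],
            root=d["root"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "markers": self.marker_names,
                    "edges": [list(e) for e in self.edges],
                    "root": self.root,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------- #
# labels / trials / windows
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class LabelSet:
    """Session-level clinical labels broadcast to every window of a trial."""

    med_state: str
    fog_score: int
    updrs_minus_fog: int
    group: str = "PD-FOG"
    age_years: float = 68.0
    sex: str = "M"

    def __post_init__(self):
        if self.med_state not in MED_STATES:
            raise ValueError(f"med_state must be one of {MED_STATES}")
        if not 0 <= self.fog_score <= 4:
            raise ValueError("fog_score must be in 0..4")
        if not 0 <= self.updrs_minus_fog <= 120:
            raise ValueError("updrs_minus_fog must be in 0..120")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass
class MarkerSequence:
    """One trial: N markers x 3 channels (x, y, z) x T samples, millimetres."""

    subject_id: str
    med_state: str
    trial_id: str
    coords: np.ndarray  # (N, 3, T)
    labels: LabelSet
    fs: float = 120.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3, T)")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.med_state, self.trial_id)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[2]


@dataclass
class AnalysisWindow:
    """Fixed-length slice of a trial plus its three task labels."""

    X: np.ndarray  # (N, 3, T)
    start_index: int
    source: tuple  # (subject_id, med_state, trial_id)
    labels: LabelSet


@dataclass
class FoldSplit:
    """One grouped random resample: whole trials assigned to train/val/test."""

    fold_id: int
    train: list[int]
    val: list[int]
    test: list[int]
    group_key: str = "trial"

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("fold splits are not disjoint")


# ---------------------------------------------------------------------- #
# IO
# ---------------------------------------------------------------------- #
def trial_filename(subject_id: str, med_state: str, trial_id: str) -> str:
    return f"{subject_id}_{med_state}_{trial_id}.csv"


def write_trial_csv(seq: MarkerSequence, skeleton: SkeletonGraph, path) -> None:
    t = np.arange(seq.n_samples) / seq.fs
    cols = {"time_s": t}
    for m, name in enumerate(skeleton.marker_names):
        for c, ax in enumerate(("x", "y", "z")):
            cols[f"{name}_{ax}"] = seq.coords[m, c]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.3f")


def write_cohort(
    trials: list[MarkerSequence], skeleton: SkeletonGraph, out_dir
) -> None:
    """Write one CSV per trial, the skeleton JSON and the label sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skeleton.to_json(out_dir / "skeleton.json")
    sidecar = []
    for seq in trials:
        fname = trial_filename(*seq.key)
        write_trial_csv(seq, skeleton, out_dir / fname)
        lab = seq.labels
        sidecar.append(
            {
                "subject_id": seq.subject_id,
                "med_state": seq.med_state,
                "trial_id": seq.trial_id,
                "file": fname,
                "fs": seq.fs,
                "fog_score": lab.fog_score,
                "updrs_minus_fog": lab.updrs_minus_fog,
                "group": lab.group,
                "age_years": lab.age_years,
                "sex": lab.sex,
            }
        )
    with open(out_dir / "labels.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trials(path, skeleton: SkeletonGraph | None = None) -> list[MarkerSequence]:
    """Read a cohort directory of trial CSVs plus the label sidecar.

    Each CSV has a `time_s` column followed by `<MARKER>_x|_y|_z` columns;
    marker order in memory follows the skeleton config, not file column
    order.
    """
    path = Path(path)
    if skeleton is None:
        skeleton = SkeletonGraph.from_json(path / "skeleton.json")
    with open(path / "labels.json") as fh:
        sidecar = json.load(fh)
    trials = []
    for rec in sidecar:
        df = pd.read_csv(path / rec["file"])
        if len(df) == 0:
            raise ValueError(f"{rec['file']}: no samples")
        t = df["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"{rec['file']}: non-monotone time column")
        N, T = skeleton.n_markers, len(df)
        coords = np.empty((N, 3, T))
        for m, name in enumerate(skeleton.marker_names):
            for c, ax in enumerate(("x", "y", "z")):
                col = f"{name}_{ax}"
                if col not in df.columns:
                    raise ValueError(f"{rec['file']}: missing marker column {name}")
                coords[m, c] = df[col].to_numpy()
        labels = LabelSet(
            med_state=rec["med_state"],
            fog_score=int(rec["fog_score"]),
            updrs_minus_fog=int(rec["updrs_minus_fog"]),
            group=rec.get("group", "PD-FOG"),
            age_years=float(rec.get("age_years", 68.0)),
            sex=rec.get("sex", "M"),
        )
        trials.append(
            MarkerSequence(
                subject_id=rec["subject_id"],
                med_state=rec["med_state"],
                trial_id=rec["trial_id"],
                coords=coords,
                labels=labels,
                fs=float(rec.get("fs", 120.0)),
            )
        )
    return trials


# ---------------------------------------------------------------------- #
# preprocessing
# ---------------------------------------------------------------------- #
def hip_center_normalize(
    seq: MarkerSequence, root_index: int, sd_floor: float = 1e-8
) -> MarkerSequence:
    """Project to a hip-centered frame, then z-normalize each channel.

    The root (hip-center) trajectory is subtracted from every marker per
    sample; each of the N*3 channels is then standardized to zero mean
    and unit SD over the trial.  Channels with SD below `sd_floor`
    (including the root itself, which becomes identically zero) are set
    to all-zeros.
    """
    if not np.all(np.isfinite(seq.coords[root_index])):
        raise ValueError("root marker contains non-finite values")
    centered = seq.coords - seq.coords[root_index : root_index + 1]
    mu = centered.mean(axis=2, keepdims=True)
    sd = centered.std(axis=2, keepdims=True)
    out = np.where(sd < sd_floor, 0.0, (centered - mu) / np.where(sd < sd_floor, 1.0, sd))
    return replace(seq, coords=out)


def segment_windows(
    seq: MarkerSequence, window_seconds: float = 4.0, stride_seconds: float = 1.0
) -> list[AnalysisWindow]:
    """Cut a trial into fixed windows (default 4 s) at a fixed stride (1 s)."""
    T = int(round(window_seconds * seq.fs))
    stride = int(round(stride_seconds * seq.fs))
    total = seq.n_samples
    if total < T:
        warnings.warn(
            f"trial {seq.key} shorter than one window ({total} < {T} samples)",
            stacklevel=2,
        )
        return []
    offsets = range(0, total - T + 1, stride)
    return [
        AnalysisWindow(
            X=seq.coords[:, :, o : o + T],
            start_index=o,
            source=seq.key,
            labels=seq.labels,
        )
        for o in offsets
    ]


# ---------------------------------------------------------------------- #
# grouped folds
# ---------------------------------------------------------------------- #
def make_folds(
    windows: list[AnalysisWindow],
    n_folds: int = 10,
    fractions: tuple = (0.5, 0.2, 0.3),
    seed: int = 0,
) -> list[FoldSplit]:
    """Build grouped random resamples at the given train/val/test fractions.

    Evaluation uses repeated random resampling: each of the `n_folds`
    draws assigns whole trials (the grouping unit, so overlapping
    windows never leak across splits) to train/validation/test,
    targeting the window-count fractions.  Deterministic given `seed`.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    keys = [w.source for w in windows]
    trial_keys = sorted(set(keys))
    if len(trial_keys) < 3:
        raise ValueError("need at least 3 trials to build folds")
    counts = {k: 0 for k in trial_keys}
    for k in keys:
        counts[k] += 1
    total = len(windows)
    rng = np.random.default_rng(seed)
    folds = []
    for f in range(n_folds):
        order = rng.permutation(len(trial_keys))
        assigned = {0: [], 1: [], 2: []}
        sizes = np.zeros(3)
        targets = np.array(fractions) * total
        for ti in order:
            key = trial_keys[ti]
            # assign to the split with the largest remaining deficit
            deficit = (targets - sizes) / targets
            split = int(np.argmax(deficit))
            assigned[split].append(ti)
            sizes[split] += counts[key]
        win_by_trial = {k: [] for k in trial_keys}
        for wi, k in enumerate(keys):
            win_by_trial[k].append(wi)
        parts = []
        for split in range(3):
            part = []
            for ti in assigned[split]:
                part.extend(win_by_trial[trial_keys[ti]])
            parts.append(sorted(part))
        folds.append(FoldSplit(fold_id=f, train=parts[0], val=parts[1], test=parts[2]))
    return folds


# ---------------------------------------------------------------------- #
# window stacking / caching
# ---------------------------------------------------------------------- #
def stack_windows(windows: list[AnalysisWindow]):
    """Stack windows into arrays for training: X (M,N,3,T) and label vectors."""
    X = np.stack([w.X for w in windows]).astype(np.float32)
    med = np.array([MED_STATES.index(w.labels.med_state) for w in windows])
    fog = np.array([w.labels.fog_score for w in windows])
    updrs = np.array([w.labels.updrs_minus_fog for w in windows], dtype=np.float64)
    return X, med, fog, updrs


def cache_windows(windows: list[AnalysisWindow], path) -> None:
    """Persist stacked windows plus provenance in one HDF5 container."""
    import h5py

    X, med, fog, updrs = stack_windows(windows)
    prov = np.array(
        ["|".join(map(str, w.source)) + f"@{w.start_index}" for w in windows],
        dtype=h5py.string_dtype(),
    )
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=X, compression="gzip")
        fh.create_dataset("med", data=med)
        fh.create_dataset("fog", data=fog)
        fh.create_dataset("updrs", data=updrs)
        fh.create_dataset("provenance", data=prov)


def load_cached_windows(path):
    import h5py

    with h5py.File(path, "r") as fh:
        return (
            fh["X"][:],
            fh["med"][:],
            fh["fog"][:],
            fh["updrs"][:],
            [p.decode() for p in fh["provenance"][:]],
        )
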
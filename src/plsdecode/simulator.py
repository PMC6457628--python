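"""Block-design 2-D fMRI simulator with Rician noise (SimTB-style).

Each run is a sequence of 2-D images: sixteen 12-s task blocks (four blocks
for each of four tasks, order randomized) alternating with seventeen 6-s rest
blocks, TR 2 s — 147 volumes per run.  Images default to 270 x 270 pixels at
a baseline intensity of 800.  Each task's HRF-convolved boxcar, scaled by
``amplitude = CNR * sigma``, is added inside that task's region of interest;
one shared region receives the sum of all four regressors.  Magnitude-image
noise is Rician: ``out = sqrt((v + n1)^2 + n2^2)`` with independent Gaussian
``n1, n2 ~ N(0, sigma^2)``.  Optional rigid 2-D translation (random walk,
bilinear resampling) emulates head motion.

Ground truth (ROI masks, paradigms, per-run seeds) is stored so selection and
decoding performance can be scored against the generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "REST",
    "Paradigm",
    "RoiLayout",
    "SubjectDataset",
    "SimulatedStudy",
    "canonical_hrf",
    "build_regressors",
    "default_layout",
    "render_run",
    "generate_study",
]

REST = 0  # label for rest volumes; tasks are 1..n_tasks

DEFAULT_TR = 2.0
DEFAULT_TASK_BLOCK_S = 12.0
DEFAULT_REST_BLOCK_S = 6.0
DEFAULT_N_TASKS = 4
DEFAULT_BLOCKS_PER_TASK = 4
DEFAULT_BASELINE = 800.0
DEFAULT_SHAPE = (270, 270)
DEFAULT_SIGMA = 30.0  # Rician noise scale in image units; amplitude = CNR * sigma
DEFAULT_CNR_LEVELS = (0.05, 0.1, 0.2, 0.4)
DEFAULT_N_SUBJECTS = 15


@dataclass
class Paradigm:
    """Ordered (label, duration) blocks plus the repetition time."""

    tr: float
    blocks: list  # list of (label:int, duration_s:float); label REST==0 for rest

    def __post_init__(self):
        total = sum(d for _, d in self.blocks)
        if abs(total / self.tr - round(total / self.tr)) > 1e-9:
            raise ValueError("total paradigm duration is not divisible by TR")

    @classmethod
    def block_design(
        cls,
        rng: np.random.Generator,
        tr: float = DEFAULT_TR,
        n_tasks: int = DEFAULT_N_TASKS,
        blocks_per_task: int = DEFAULT_BLOCKS_PER_TASK,
        task_s: float = DEFAULT_TASK_BLOCK_S,
        rest_s: float = DEFAULT_REST_BLOCK_S,
    ) -> "Paradigm":
        """Randomized task order, rest blocks interleaved (rest first and last)."""
        order = rng.permutation(np.repeat(np.arange(1, n_tasks + 1), blocks_per_task))
        blocks = [(REST, rest_s)]
        for task in order:
            blocks.append((int(task), task_s))
            blocks.append((REST, rest_s))
        return cls(tr=tr, blocks=blocks)

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.blocks)

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration / self.tr))

    @property
    def n_tasks(self) -> int:
        return max(label for label, _ in self.blocks)

    def volume_labels(self, shift_s: float = 0.0) -> np.ndarray:
        """Label of the block covering each volume's onset (REST for rest).

        ``shift_s`` shifts labels forward by the hemodynamic lag: volume i is
        labeled by the block covering ``i*TR - shift_s`` (REST before time 0),
        so labels refer to the stimulus the measured BOLD signal responds to.
        """
        labels = np.empty(self.n_volumes, dtype=int)
        edges, t = [], 0.0
        for label, dur in self.blocks:
            edges.append((t, t + dur, label))
            t += dur
        for i in range(self.n_volumes):
            onset = i * self.tr - shift_s
            labels[i] = REST
            for lo, hi, label in edges:
                if lo <= onset < hi:
                    labels[i] = label
                    break
        return labels

    def boxcars(self) -> np.ndarray:
        """(n_volumes, n_tasks) 0/1 matrix: 1 while that task's block is on."""
        labels = self.volume_labels()
        out = np.zeros((self.n_volumes, self.n_tasks))
        for j in range(1, self.n_tasks + 1):
            out[:, j - 1] = labels == j
        return out

    def block_counts(self) -> dict:
        counts: dict = {}
        for label, _ in self.blocks:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def to_events(self):
        """BIDS-style events table (onset, duration, trial_type)."""
        import pandas as pd

        rows, t = [], 0.0
        for label, dur in self.blocks:
            rows.append(
                {
                    "onset": t,
                    "duration": dur,
                    "trial_type": "rest" if label == REST else f"task{label}",
                }
            )
            t += dur
        return pd.DataFrame(rows)


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR, peak = 1.

    Response gamma: shape 6, scale 1 (delay 6 s); undershoot gamma: shape 16,
    scale 1 (delay 16 s), weighted 1/6.  Kernel length 32 s, onset 0.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration + tr / 2, tr)
    h = stats.gamma.pdf(t, a=6, scale=1) - stats.gamma.pdf(t, a=16, scale=1) / 6.0
    return h / h.max()


def build_regressors(paradigm: Paradigm, hrf: np.ndarray | None = None) -> np.ndarray:
    """(n_volumes, n_tasks) HRF-convolved boxcars, truncated to run length."""
    if hrf is None:
        hrf = canonical_hrf(paradigm.tr)
    box = paradigm.boxcars()
    n = box.shape[0]
    out = np.empty_like(box)
    for j in range(box.shape[1]):
        out[:, j] = np.convolve(box[:, j], hrf)[:n]
    return out


@dataclass
class RoiLayout:
    """Four disjoint task ROIs plus one shared ROI on a 2-D grid."""

    shape: tuple
    task_masks: list  # list of (H, W) bool arrays
    shared_mask: np.ndarray
    baseline: float = DEFAULT_BASELINE

    def __post_init__(self):
        stack = np.stack(self.task_masks + [self.shared_mask]).astype(int)
        if np.any(stack.sum(axis=0) > 1):
            raise ValueError("ROI masks overlap")
        if any(m.sum() == 0 for m in self.task_masks) or self.shared_mask.sum() == 0:
            raise ValueError("empty ROI mask")
        for m in self.task_masks + [self.shared_mask]:
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape does not match grid")

    @property
    def n_tasks(self) -> int:
        return len(self.task_masks)

    def flat_task_indices(self, task: int) -> np.ndarray:
        """Flat voxel indices of task ROI (task in 1..n_tasks)."""
        return np.flatnonzero(self.task_masks[task - 1].ravel())

    def flat_shared_indices(self) -> np.ndarray:
        return np.flatnonzero(self.shared_mask.ravel())


def default_layout(
    shape: tuple = DEFAULT_SHAPE,
    roi_frac: float = 0.07,
    baseline: float = DEFAULT_BASELINE,
) -> RoiLayout:
    """Parametric layout: four square task ROIs in the quadrants, shared ROI center.

    The ROI side scales with the grid (``roi_frac`` of the smaller dimension),
    so reduced-resolution studies preserve the ROI proportions.
    """
    h, w = shape
    side = max(3, int(round(roi_frac * min(h, w))))
    centers = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]

    def square(cy, cx):
        m = np.zeros(shape, dtype=bool)
        y0 = int(round(cy * h - side / 2))
        x0 = int(round(cx * w - side / 2))
        m[y0 : y0 + side, x0 : x0 + side] = True
        return m

    task_masks = [square(cy, cx) for cy, cx in centers]
    shared = square(0.5, 0.5)
    return RoiLayout(shape=shape, task_masks=task_masks, shared_mask=shared,
                     baseline=baseline)


def add_rician_noise(clean: np.ndarray, sigma: float, rng: np.random.Generator):
    """Magnitude-image corruption sqrt((v + n1)^2 + n2^2), n1,n2 ~ N(0, sigma^2)."""
    if sigma == 0:
        return clean.copy()
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)


def render_run(
    layout: RoiLayout,
    regressors: np.ndarray,
    amplitude: float,
    noise_sigma: float,
    rng: np.random.Generator,
    motion: float = 0.0,
) -> np.ndarray:
    """Render one run: (n_volumes, H, W) array.

    Pixel value before noise = baseline + amplitude * (own-task regressor in a
    task ROI; sum of all regressors in the shared ROI; 0 elsewhere).  Optional
    motion applies a per-volume random-walk translation (step sd = ``motion``
    pixels, bilinear resampling) before the Rician corruption.
    """
    n, q = regressors.shape
    if q != layout.n_tasks:
        raise ValueError("regressor count does not match layout tasks")
    h, w = layout.shape
    clean = np.full((n, h, w), layout.baseline, dtype=float)
    for j in range(q):
        clean[:, layout.task_masks[j]] += amplitude * regressors[:, j, None]
    clean[:, layout.shared_mask] += amplitude * regressors.sum(axis=1)[:, None]
    if motion > 0:
        shifts = np.cumsum(rng.normal(0.0, motion, size=(n, 2)), axis=0)
        for i in range(n):
            clean[i] = ndimage.shift(
                clean[i], shifts[i], order=1, mode="nearest"
            )
    return add_rician_noise(clean, noise_sigma, rng)


@dataclass
class SubjectDataset:
    """Two rendered runs with their paradigms and per-volume labels."""

    subject: int
    cnr: float
    runs: list  # list of (data (n,H,W), labels (n,)) tuples
    paradigms: list


@dataclass
class SimulatedStudy:
    """Multi-subject, multi-CNR study definition with deterministic rendering.

    Datasets are rendered on demand from seeds derived from the master seed
    (``SeedSequence(master, spawn_key=(cnr_index, subject, run))``), so the
    same master seed always reproduces bit-identical data without holding the
    whole study in memory.
    """

    cnr_levels: tuple = DEFAULT_CNR_LEVELS
    n_subjects: int = DEFAULT_N_SUBJECTS
    seed: int = 0
    shape: tuple = DEFAULT_SHAPE
    sigma: float = DEFAULT_SIGMA
    tr: float = DEFAULT_TR
    motion: float = 0.0
    label_shift_s: float = 4.0  # hemodynamic lag applied to decoding labels
    runs_per_subject: int = 2
    layout: RoiLayout = field(default=None)

    def __post_init__(self):
        if any(c < 0 for c in self.cnr_levels):
            raise ValueError("CNR must be >= 0")
        if self.layout is None:
            self.layout = default_layout(self.shape)

    @property
    def n_datasets(self) -> int:
        return len(self.cnr_levels) * self.n_subjects

    def _rng(self, cnr: float, subject: int, run: int) -> np.random.Generator:
        ci = list(self.cnr_levels).index(cnr)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(ci, subject, run))
        )

    def paradigm(self, cnr: float, subject: int, run: int) -> Paradigm:
        return Paradigm.block_design(self._rng(cnr, subject, run), tr=self.tr)

    def render(self, cnr: float, subject: int, run: int):
        """Deterministically render one run; returns (data, labels, paradigm)."""
        rng = self._rng(cnr, subject, run)
        paradigm = Paradigm.block_design(rng, tr=self.tr)
        regs = build_regressors(paradigm)
        amplitude = cnr * self.sigma
        data = render_run(
            self.layout, regs, amplitude, self.sigma, rng, motion=self.motion
        )
        return data, paradigm.volume_labels(self.label_shift_s), paradigm

    def dataset(self, cnr: float, subject: int) -> SubjectDataset:
        runs, paradigms = [], []
        for run in range(self.runs_per_subject):
            data, labels, paradigm = self.render(cnr, subject, run)
            runs.append((data, labels))
            paradigms.append(paradigm)
        return SubjectDataset(subject=subject, cnr=cnr, runs=runs,
                              paradigms=paradigms)


def generate_study(
    cnr_levels=DEFAULT_CNR_LEVELS,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    seed: int = 0,
    **kwargs,
) -> SimulatedStudy:
    """Build a :class:`SimulatedStudy` (lazy, deterministic per master seed)."""
    return SimulatedStudy(
        cnr_levels=tuple(cnr_levels), n_subjects=n_subjects, seed=seed, **kwargs
    )
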
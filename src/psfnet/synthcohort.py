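"""Synthetic two-cohort regional time series with known coupling structure.

Each region emits a sinusoid of its driver group's slowly wandering
phase, plus per-region phase jitter and amplitude noise. Case subjects
additionally receive, on the endpoints of a planted edge set, a shared
extra oscillatory component — an "additional network" superimposed on
the base structure, raising pairwise phase synchrony on exactly those
pairs. The planted component enters with a fixed phase lag between edge
endpoints (default pi/2), so it is visible to phase-synchrony estimators
but carries almost no Pearson-correlation signal.

All randomness flows from explicit integer seeds; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CohortSpec",
    "SubjectTimeSeries",
    "CohortTruth",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_MIN_SAMPLES = 32


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's regions x time signal matrix."""

    subject_id: str
    group_label: str
    data: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.group_label not in ("case", "control"):
            raise ValueError(f"group_label must be case/control, got {self.group_label!r}")
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if data.shape[1] < _MIN_SAMPLES:
            raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {data.shape[1]}")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains missing or non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a two-cohort synthetic study.

    ``base_communities`` partitions region indices 1..n_regions into
    driver groups; singleton groups yield mutually independent regions.
    ``additional_edges`` are unordered region pairs planted in case
    subjects only. Jitter scales are standard deviations in radians of
    the per-sample wrapped-Gaussian phase jitter.
    """

    n_regions: int
    n_samples: int = 197
    sampling_interval: float = 2.0
    base_communities: tuple[tuple[int, ...], ...] = ()
    base_coupling: float | tuple[float, ...] = 0.3
    additional_edges: tuple[tuple[int, int], ...] = ()
    additional_coupling: float = 0.1
    additional_amplitude: float = 1.5
    planted_phase_lag: float = np.pi / 2
    noise_sd: float = 0.1
    driver_freq_band: tuple[float, float] = (0.01, 0.08)
    drift_sd: float = 0.05
    slot_drivers: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions: must be >= 2")
        if self.n_samples < _MIN_SAMPLES:
            raise ValueError(f"n_samples: must be >= {_MIN_SAMPLES}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval: must be > 0")
        if not self.base_communities:
            object.__setattr__(
                self, "base_communities", tuple((i,) for i in range(1, self.n_regions + 1))
            )
        groups = [tuple(int(i) for i in g) for g in self.base_communities]
        object.__setattr__(self, "base_communities", tuple(groups))
        flat = sorted(i for g in groups for i in g)
        if flat != list(range(1, self.n_regions + 1)):
            raise ValueError("base_communities: must partition regions 1..n_regions")
        coupling = self.base_coupling
        if np.isscalar(coupling):
            coupling = (float(coupling),) * len(groups)
        coupling = tuple(float(c) for c in coupling)
        if len(coupling) != len(groups):
            raise ValueError("base_coupling: one scale per driver group (or a scalar)")
        if any(c < 0 for c in coupling):
            raise ValueError("base_coupling: scales must be >= 0")
        object.__setattr__(self, "base_coupling", coupling)
        edges = []
        for e in self.additional_edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"additional_edges: self-pair ({i},{j}) not allowed")
            if not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions):
                raise ValueError(f"additional_edges: pair ({i},{j}) out of range")
            edges.append((min(i, j), max(i, j)))
        if len(set(edges)) != len(edges):
            raise ValueError("additional_edges: duplicate pairs")
        object.__setattr__(self, "additional_edges", tuple(sorted(edges)))
        if self.additional_coupling < 0:
            raise ValueError("additional_coupling: must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be >= 0")
        low, high = self.driver_freq_band
        nyquist = 0.5 / self.sampling_interval
        if not 0.0 < low < high < nyquist:
            raise ValueError(
                f"driver_freq_band: ({low}, {high}) must lie inside (0, {nyquist:g}) Hz"
            )
        if self.drift_sd < 0:
            raise ValueError("drift_sd: must be >= 0")


@dataclass(frozen=True)
class CohortTruth:
    """Planted structure and the per-subject seeds that generated a cohort."""

    planted_edges: tuple[tuple[int, int], ...]
    subject_seeds: dict[str, int]


def _planted_components(edges) -> list[list[int]]:
    """Connected components of the planted edge set, each sorted."""
    parent: dict[int, int] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ra, rb = find(i), find(j)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for node in parent:
        comps.setdefault(find(node), []).append(node)
    return [sorted(c) for c in sorted(comps.values())]


def _driver_phase(
    rng: np.random.Generator, spec: CohortSpec, slot: int, n_slots: int
) -> np.ndarray:
    """Wandering driver phase: in-band carrier plus a phase random walk.

    With ``slot_drivers`` each driver occupies its own frequency slot
    inside the band (carrier jittered within the slot), so distinct
    drivers never collide in frequency and unrelated regions decohere
    over the scan; otherwise carriers are drawn uniformly in the band.
    """
    low, high = spec.driver_freq_band
    if spec.slot_drivers:
        width = (high - low) / n_slots
        freq = low + width * (slot + 0.3 + 0.4 * rng.uniform())
    else:
        freq = rng.uniform(low, high)
    t = np.arange(spec.n_samples) * spec.sampling_interval
    wander = np.cumsum(rng.normal(0.0, spec.drift_sd, size=spec.n_samples))
    return 2.0 * np.pi * freq * t + wander + rng.uniform(0.0, 2.0 * np.pi)


def generate_subject(spec: CohortSpec, group: str, subject_seed: int) -> SubjectTimeSeries:
    """One subject's regions x time matrix, deterministic in (spec, group, seed)."""
    if group not in ("case", "control"):
        raise ValueError(f"group must be case/control, got {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(subject_seed)]))
    components = _planted_components(spec.additional_edges)
    n_slots = len(spec.base_communities) + len(components)
    data = np.zeros((spec.n_regions, spec.n_samples))
    for g_idx, members in enumerate(spec.base_communities):
        theta = _driver_phase(rng, spec, g_idx, n_slots)
        jitter_scale = spec.base_coupling[g_idx]
        for region in members:
            offset = rng.uniform(0.0, 2.0 * np.pi)
            jitter = rng.normal(0.0, jitter_scale, size=spec.n_samples) if jitter_scale else 0.0
            data[region - 1] += np.sin(theta + offset + jitter)
    if group == "case" and spec.additional_edges:
        for c_idx, comp in enumerate(components):
            theta = _driver_phase(rng, spec, len(spec.base_communities) + c_idx, n_slots)
            for pos, region in enumerate(comp):
                offset = pos * spec.planted_phase_lag
                if spec.additional_coupling:
                    jitter = rng.normal(0.0, spec.additional_coupling, size=spec.n_samples)
                else:
                    jitter = 0.0
                data[region - 1] += spec.additional_amplitude * np.sin(theta + offset + jitter)
    if spec.noise_sd:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return SubjectTimeSeries(
        subject_id=f"{group}_{subject_seed}",
        group_label=group,
        data=data,
        sampling_interval=spec.sampling_interval,
    )


def generate_cohort(
    spec: CohortSpec, n_control: int, n_case: int, seed: int
) -> tuple[list[SubjectTimeSeries], CohortTruth]:
    """Generate ``n_control + n_case`` subjects with deterministic per-subject seeds."""
    if n_control < 1 or n_case < 1:
        raise ValueError("n_control and n_case must each be >= 1")
    seed_rng = np.random.default_rng(np.random.SeedSequence([int(seed), spec.seed]))
    subject_seeds = seed_rng.integers(0, 2**31 - 1, size=n_control + n_case)
    subjects: list[SubjectTimeSeries] = []
    seeds: dict[str, int] = {}
    for k in range(n_control):
        s = int(subject_seeds[k])
        subj = replace(
            generate_subject(spec, "control", s), subject_id=f"control_{k + 1:02d}"
        )
        subjects.append(subj)
        seeds[subj.subject_id] = s
    for k in range(n_case):
        s = int(subject_seeds[n_control + k])
        subj = replace(generate_subject(spec, "case", s), subject_id=f"case_{k + 1:02d}")
        subjects.append(subj)
        seeds[subj.subject_id] = s
    return subjects, CohortTruth(planted_edges=spec.additional_edges, subject_seeds=seeds)


def write_cohort(
    subjects: list[SubjectTimeSeries], truth: CohortTruth, out_dir: str | Path
) -> Path:
    """Write per-subject TSVs, a manifest, and the planted-edge truth file."""
    out_dir = Path(out_dir)
    subj_dir = out_dir / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["subject_id\tgroup\tsampling_interval\tpath"]
    for subj in subjects:
        rel = f"subjects/{subj.subject_id}.tsv"
        np.savetxt(out_dir / rel, subj.data, delimiter="\t", fmt="%.8g")
        manifest_lines.append(
            f"{subj.subject_id}\t{subj.group_label}\t{subj.sampling_interval:g}\t{rel}"
        )
    (out_dir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    truth_lines = ["region_i\tregion_j"]
    truth_lines += [f"{i}\t{j}" for i, j in truth.planted_edges]
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    return out_dir / "manifest.tsv"


def read_cohort(manifest_path: str | Path) -> list[SubjectTimeSeries]:
    """Load a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    lines = manifest_path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["subject_id", "group", "sampling_interval", "path"]:
        raise ValueError(f"{manifest_path}: not a cohort manifest")
    subjects = []
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, group, dt, rel = line.split("\t")
        data = np.loadtxt(root / rel, delimiter="\t")
        subjects.append(SubjectTimeSeries(sid, group, data, float(dt)))
    return subjects
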
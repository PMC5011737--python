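"""Synthetic data with known ground truth for every pipeline stage.

Three generators: correlated-random-walk swimming trajectories in a circular
arena (emulating video-tracked amphipods in a petri dish), grouped
sample x taxon count tables with a controllable between-group effect size
(a stand-in for 16S OTU tables from stygofauna and groundwater samples), and
random rooted binary trees with branch lengths for phylogenetic-diversity
rarefaction.

One global seed fans out to independent per-component streams through
``numpy.random.SeedSequence.spawn``, so outputs are bit-identical across
runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .kinematics import Trajectory

__all__ = [
    "TrajectorySpec",
    "CommunitySpec",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_community",
    "simulate_tree",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Conditions of the swimming-speed video experiment.

    Defaults mirror the laboratory setup the kinematics are calibrated
    against: eleven amphipods filmed at 30 frames per second in a 16.34 cm
    petri dish, five replicates each, cohort mean speed 6.9e4 m yr^-1 with a
    coefficient of variation of 4.6/6.9 ~ 0.67.
    """

    n_individuals: int = 11
    mean_speed_m_yr: float = 6.9e4
    speed_cv: float = 4.6 / 6.9
    replicates_per_individual: int = 5
    fps: float = 30.0
    duration_s: float = 60.0
    arena_diameter_cm: float = 16.34
    turn_sd_rad: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.replicates_per_individual < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_speed_m_yr <= 0:
            raise ValueError("mean speed must be positive")
        if not 0 <= self.speed_cv < 2:
            raise ValueError("speed_cv must be in [0, 2)")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        if self.arena_diameter_cm <= 0:
            raise ValueError("arena diameter must be positive")
        if self.turn_sd_rad < 0:
            raise ValueError("turn_sd_rad must be >= 0")


@dataclass(frozen=True)
class CommunitySpec:
    """Grouped community tables with a known between-group effect.

    Each group's mean composition is the shared Dirichlet-drawn base
    composition shifted by ``effect_size`` along a random direction in
    log-composition space (then renormalized), so ``effect_size = 0`` makes
    the groups exchangeable by construction.  Counts are multinomial at
    lognormally distributed sequencing depths.
    """

    groups: tuple[tuple[str, int], ...] = (("body", 8), ("leg", 8), ("groundwater", 8))
    n_taxa: int = 50
    base_composition_concentration: float = 1.0
    effect_size: float = 1.0
    depth_mean: float = 10_000.0
    depth_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple((str(g), int(n)) for g, n in self.groups))
        if any(n < 1 for _, n in self.groups) or len(self.groups) < 1:
            raise ValueError("every group needs n_samples >= 1")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.base_composition_concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")


def _lognormal_arithmetic(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _speed_to_step_cm(target_speed_m_yr: float, fps: float) -> float:
    # m yr^-1 -> cm per frame: x100 cm/m, /525,600 min/yr, /60 s/min, /fps
    return target_speed_m_yr * 100.0 / 525_600.0 / 60.0 / fps


def simulate_trajectory(
    spec: TrajectorySpec,
    target_speed_m_yr: float,
    rng: np.random.Generator | None = None,
    individual_id: str = "sim",
    replicate: int = 1,
) -> Trajectory:
    """One correlated random walk confined to the circular arena.

    The walker starts at the arena centre with a random initial heading and
    takes one fixed-length step per frame (the step is the target speed
    converted to cm/frame); turning angles between frames are i.i.d. normal
    with SD ``spec.turn_sd_rad``.  The arena wall reflects specularly, which
    preserves the within-frame path length, so the realized path-length speed
    equals the target up to the duration discretization (within 1% absent
    reflections; reflections themselves do not change path length but the
    *chord* recorded between frame positions shortens slightly).
    """
    if target_speed_m_yr < 0:
        raise ValueError("target speed must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_s * spec.fps))
    if n_steps < 1:
        raise ValueError("duration x fps must give at least one step")
    step = _speed_to_step_cm(target_speed_m_yr, spec.fps)
    radius = spec.arena_diameter_cm / 2.0

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.normal(0.0, spec.turn_sd_rad, size=n_steps)
    turns[0] = 0.0
    headings = theta0 + np.cumsum(turns)
    dx = step * np.cos(headings)
    dy = step * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])

    if np.any(np.hypot(x, y) > radius):  # rare from a centre start: redo with walls
        x, y = _walk_with_reflection(step, headings, radius)

    t = np.arange(n_steps + 1) / spec.fps
    return Trajectory(individual_id=individual_id, replicate=replicate,
                      t_s=t, x_cm=x, y_cm=y)


def _walk_with_reflection(step: float, headings: np.ndarray, radius: float):
    """Sequential walk with specular reflection at the circular wall."""
    n = headings.size
    x = np.zeros(n + 1)
    y = np.zeros(n + 1)
    heading_offset = 0.0
    for j in range(n):
        th = headings[j] + heading_offset
        px, py = x[j], y[j]
        vx, vy = step * np.cos(th), step * np.sin(th)
        # reflect as often as needed within this frame (usually 0 or 1 times)
        for _ in range(16):
            qx, qy = px + vx, py + vy
            if np.hypot(qx, qy) <= radius:
                break
            # fraction of the step at which the wall is hit
            a = vx**2 + vy**2
            b = 2.0 * (px * vx + py * vy)
            c = px**2 + py**2 - radius**2
            t_hit = (-b + np.sqrt(max(b**2 - 4 * a * c, 0.0))) / (2 * a)
            t_hit = min(max(t_hit, 0.0), 1.0)
            hx, hy = px + t_hit * vx, py + t_hit * vy
            nx, ny = hx / radius, hy / radius
            rx, ry = (1.0 - t_hit) * vx, (1.0 - t_hit) * vy
            dot = rx * nx + ry * ny
            vx, vy = rx - 2.0 * dot * nx, ry - 2.0 * dot * ny
            px, py = hx, hy
        else:
            px, py = qx, qy  # pragma: no cover - numerical corner
            vx = vy = 0.0
        x[j + 1], y[j + 1] = px + vx, py + vy
        new_heading = np.arctan2(vy, vx) if (vx or vy) else th
        heading_offset += new_heading - th
    return x, y


def simulate_cohort(spec: TrajectorySpec) -> list[Trajectory]:
    """Trajectories for a cohort: ``n_individuals x replicates_per_individual``.

    Each individual's target speed is one lognormal draw with arithmetic mean
    ``mean_speed_m_yr`` and CV ``speed_cv``; all of its replicates swim at
    that target (replicate-to-replicate speed variation is not modeled).
    """
    root = np.random.SeedSequence(spec.seed)
    speed_seq, *walk_seqs = root.spawn(1 + spec.n_individuals * spec.replicates_per_individual)
    speed_rng = np.random.default_rng(speed_seq)
    targets = _lognormal_arithmetic(
        speed_rng, spec.mean_speed_m_yr, spec.speed_cv, spec.n_individuals
    )
    out: list[Trajectory] = []
    k = 0
    for i, target in enumerate(targets, start=1):
        for r in range(1, spec.replicates_per_individual + 1):
            rng = np.random.default_rng(walk_seqs[k])
            k += 1
            out.append(
                simulate_trajectory(
                    spec, float(target), rng=rng,
                    individual_id=f"individual_{i:02d}", replicate=r,
                )
            )
    return out


def simulate_community(spec: CommunitySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped multinomial count table with a log-composition group effect.

    Returns
    -------
    counts : DataFrame
        samples x taxa integer counts; row sums equal the drawn depths.
    metadata : DataFrame
        columns ``sample_id`` and ``group``, aligned with ``counts``.
    """
    root = np.random.SeedSequence(spec.seed)
    base_seq, dir_seq, depth_seq, count_seq = root.spawn(4)

    base_rng = np.random.default_rng(base_seq)
    alpha = np.full(spec.n_taxa, spec.base_composition_concentration)
    base = base_rng.dirichlet(alpha)
    base = np.clip(base, 1e-12, None)
    log_base = np.log(base)

    dir_rng = np.random.default_rng(dir_seq)
    group_probs = {}
    for label, _ in spec.groups:
        u = dir_rng.standard_normal(spec.n_taxa)
        u /= np.linalg.norm(u)
        logits = log_base + spec.effect_size * u
        p = np.exp(logits - logits.max())
        group_probs[label] = p / p.sum()

    n_total = sum(n for _, n in spec.groups)
    depth_rng = np.random.default_rng(depth_seq)
    depths = np.maximum(
        1, np.round(_lognormal_arithmetic(depth_rng, spec.depth_mean, spec.depth_cv, n_total))
    ).astype(np.int64)
    if np.any(depths < 1):
        raise ValueError("sequencing depth below 1")

    count_rng = np.random.default_rng(count_seq)
    taxa = [f"otu{i + 1:04d}" for i in range(spec.n_taxa)]
    rows, sample_ids, labels = [], [], []
    k = 0
    for label, n_samples in spec.groups:
        for s in range(1, n_samples + 1):
            rows.append(count_rng.multinomial(depths[k], group_probs[label]))
            sample_ids.append(f"{label}_{s:02d}")
            labels.append(label)
            k += 1
    counts = pd.DataFrame(np.asarray(rows), index=pd.Index(sample_ids, name="sample_id"),
                          columns=taxa)
    metadata = pd.DataFrame({"sample_id": sample_ids, "group": labels})
    return counts, metadata


def simulate_tree(n_taxa: int, seed: int | None = None) -> str:
    """Random rooted binary tree over ``otu0001..otuNNNN`` as a newick string.

    Built by repeatedly joining two uniformly chosen subtrees under a new
    internal node; every branch gets an exponential(1) length (strictly
    positive), the root has none.  Total branch length therefore equals the
    Faith's PD of the full taxon set.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"otu{i + 1:04d}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        for child in (a, b):
            child.length = float(rng.exponential(1.0)) + 1e-6
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return str(root).strip()
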
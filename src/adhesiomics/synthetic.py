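"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here: over-dispersed
spectral-count matrices for a two-condition (active/inactive) design with
planted condition-specific enrichment, scale-free or Erdos-Renyi
interactomes containing a designated seed protein, annotation term
collections with planted enriched terms, two-state microtubule tip
trajectories with regime-dependent cortical dwell, and micropatterned
intensity images. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .network import InteractomeGraph

__all__ = [
    "SimCountConfig",
    "SimTrackConfig",
    "gen_counts",
    "gen_interactome",
    "gen_annotations",
    "gen_tracks",
    "gen_pattern_image",
]

TRUTH_CLASSES = (
    "active-enriched",
    "inactive-enriched",
    "unique-active",
    "unique-inactive",
    "null",
)


@dataclass(frozen=True)
class SimCountConfig:
    """Design of a simulated spectral-count experiment.

    Counts follow a gamma-Poisson (negative binomial) law with
    ``var = m + dispersion * m**2``; enriched proteins split the planted fold
    symmetrically (x sqrt(fold) up in one condition, / sqrt(fold) in the
    other) so overall abundance stays balanced; "unique" proteins have a
    structural zero expectation in the other condition.
    """

    n_proteins: int
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    baseline_mean: float = 50.0
    dispersion: float = 0.05
    frac_active_enriched: float = 0.0
    frac_inactive_enriched: float = 0.0
    planted_fold: float = 4.0
    frac_unique_active: float = 0.0
    frac_unique_inactive: float = 0.0
    mw_range_kda: tuple = (10.0, 500.0)
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_active_enriched
            + self.frac_inactive_enriched
            + self.frac_unique_active
            + self.frac_unique_inactive
        )
        if fracs > 1.0 + 1e-12:
            raise ValueError(f"planted fractions sum to {fracs} > 1")
        if min(
            self.frac_active_enriched,
            self.frac_inactive_enriched,
            self.frac_unique_active,
            self.frac_unique_inactive,
        ) < 0:
            raise ValueError("fractions must be non-negative")
        if self.planted_fold < 1.0:
            raise ValueError("planted_fold must be >= 1")
        if self.n_proteins < 1 or self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("counts and replicate numbers must be positive")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        lo, hi = self.mw_range_kda
        if not (0 < lo <= hi):
            raise ValueError("mw_range_kda must be positive with low <= high")


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with var = m + dispersion * m**2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean[pos] * dispersion)
        out[pos] = rng.poisson(lam)
    else:
        out[pos] = rng.poisson(mean[pos])
    return out


def gen_counts(config: SimCountConfig):
    """Simulate a 2-condition x bio x tech spectral-count experiment.

    Returns (counts, design, meta, truth):

    * counts — proteins x samples integer DataFrame;
    * design — sample_id, condition, bio_rep, tech_rep, total_spectra (the
      column sum, the observed total of the run);
    * meta — accession-indexed metadata with log-uniform molecular weights;
    * truth — accession-indexed Series of planted classes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    counts_per_class = {
        "active-enriched": int(round(config.frac_active_enriched * n)),
        "inactive-enriched": int(round(config.frac_inactive_enriched * n)),
        "unique-active": int(round(config.frac_unique_active * n)),
        "unique-inactive": int(round(config.frac_unique_inactive * n)),
    }
    labels = []
    for cls, k in counts_per_class.items():
        labels.extend([cls] * k)
    labels.extend(["null"] * (n - len(labels)))
    labels = np.array(labels[:n], dtype=object)
    rng.shuffle(labels)

    root_fold = np.sqrt(config.planted_fold)
    mean_active = np.full(n, config.baseline_mean)
    mean_inactive = np.full(n, config.baseline_mean)
    mean_active[labels == "active-enriched"] *= root_fold
    mean_inactive[labels == "active-enriched"] /= root_fold
    mean_active[labels == "inactive-enriched"] /= root_fold
    mean_inactive[labels == "inactive-enriched"] *= root_fold
    mean_inactive[labels == "unique-active"] = 0.0
    mean_active[labels == "unique-inactive"] = 0.0

    accessions = [f"P{i:05d}" for i in range(n)]
    samples, cols = [], {}
    for cond, means in (("active", mean_active), ("inactive", mean_inactive)):
        for b in range(1, config.n_bio_reps + 1):
            for t in range(1, config.n_tech_reps + 1):
                sid = f"{cond}_b{b}_t{t}"
                samples.append((sid, cond, f"b{b}", f"t{t}"))
                cols[sid] = _nbinom(rng, means, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(accessions, name="accession"))
    design = pd.DataFrame(samples, columns=["sample_id", "condition", "bio_rep", "tech_rep"])
    design["total_spectra"] = counts.sum(axis=0).reindex(design["sample_id"]).to_numpy()
    design["total_spectra"] = design["total_spectra"].clip(lower=1)

    lo, hi = config.mw_range_kda
    mw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    meta = pd.DataFrame(
        {
            "symbol": [f"GENE{i}" for i in range(n)],
            "mw_kda": mw,
            "adhesome": "none",
            "functional_class": "none",
            "is_tip": False,
        },
        index=counts.index,
    )
    truth = pd.Series(labels, index=counts.index, name="truth_class")
    return counts, design, meta, truth


def gen_interactome(
    n_nodes: int,
    n_edges: int,
    seed_node: str = "ITGB1",
    model: str = "scale-free",
    seed: int = 0,
) -> InteractomeGraph:
    """Random simple undirected interactome containing ``seed_node``.

    ``model="scale-free"`` grows a preferential-attachment graph (heavier
    degree tail); ``model="Erdos-Renyi"`` draws edges uniformly. The edge
    count is exactly ``n_edges`` in both cases.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds simple-graph maximum {max_edges}")
    if n_nodes < 1 or n_edges < 0:
        raise ValueError("n_nodes must be >= 1 and n_edges >= 0")
    rng = np.random.default_rng(seed)
    if model == "scale-free":
        m = max(1, min(round(n_edges / max(n_nodes, 1)), n_nodes - 1))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    elif model == "Erdos-Renyi":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown model {model!r}")
    # adjust to the exact edge count
    while g.number_of_edges() > n_edges:
        edges = sorted(g.edges)
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    while g.number_of_edges() < n_edges:
        u, v = rng.integers(n_nodes, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v))
    names = {i: (seed_node if i == 0 else f"P{i:05d}") for i in range(n_nodes)}
    g = nx.relabel_nodes(g, names)
    provenance = {frozenset(e): {"synthetic"} for e in g.edges}
    return InteractomeGraph(graph=g, seed=seed_node, provenance=provenance)


def gen_annotations(
    n_terms: int,
    background,
    size_range: tuple = (5, 500),
    planted: list | None = None,
    truth: pd.Series | None = None,
    seed: int = 0,
) -> dict:
    """Random annotation term collection over a protein background.

    Random terms draw members uniformly without replacement with sizes
    uniform in ``size_range``. ``planted`` entries
    ``(term_id, truth_class, purity, size)`` draw ``purity * size`` members
    from the proteins whose ``truth`` label equals ``truth_class`` and the
    remainder from the rest of the background.
    """
    background = sorted(map(str, background))
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    if hi > len(background):
        raise ValueError("background smaller than the maximum term size")
    rng = np.random.default_rng(seed)
    bg = np.array(background, dtype=object)
    terms: dict[str, set] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"T{i:04d}"] = set(bg[rng.choice(len(bg), size=size, replace=False)])
    for entry in planted or []:
        term_id, cls, purity, size = entry
        if not 0.0 <= purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if truth is None:
            raise ValueError("planted terms require truth labels")
        pool_in = [p for p in background if truth.get(p) == cls]
        pool_out = [p for p in background if truth.get(p) != cls]
        k_in = int(round(purity * size))
        k_in = min(k_in, len(pool_in))
        k_out = size - k_in
        members = set(
            np.array(pool_in, dtype=object)[
                rng.choice(len(pool_in), size=k_in, replace=False)
            ]
        )
        if k_out:
            members |= set(
                np.array(pool_out, dtype=object)[
                    rng.choice(len(pool_out), size=k_out, replace=False)
                ]
            )
        terms[str(term_id)] = members
    return terms


@dataclass(frozen=True)
class SimTrackConfig:
    """Two-state microtubule tip trajectory simulation.

    Tips grow toward the cell edge at ``growth_speed_um_per_frame``; in the
    cortical band (within ``band_um`` of the boundary) they pause for a
    geometric number of frames with mean ``cortical_dwell_frames``
    (regime-dependent: stimulatory > inhibitory), then undergo catastrophe
    and re-nucleate at an interior point under the same track id. Frames are
    sampled every ``frame_interval_s`` seconds.
    """

    boundary: object  # polygon vertex array or shapely Polygon, um
    n_microtubules: int = 200
    frame_interval_s: float = 10.0
    n_frames: int = 60
    growth_speed_um_per_frame: float = 3.0
    catastrophe_prob: float = 0.02
    cortical_dwell_frames: float = 6.0
    regime: str = "stimulatory"
    band_um: float = 2.0
    seed: int = 0


def _random_interior_point(rng, poly: Polygon, min_edge_um: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    inner = poly.buffer(-min_edge_um)
    target = inner if not inner.is_empty else poly
    for _ in range(10_000):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if target.covers(Point(p)):
            return p
    raise RuntimeError("could not sample an interior point")


def gen_tracks(config: SimTrackConfig) -> pd.DataFrame:
    """Simulate tip trajectories; returns a tidy DataFrame with columns
    mt_id, frame, t_s, x_um, y_um, state ({growth, paused}).

    All positions lie inside or on the boundary; timestamps are
    0, dt, 2 dt, ...
    """
    poly = config.boundary if isinstance(config.boundary, Polygon) else Polygon(config.boundary)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("boundary must be a simple closed polygon")
    if config.cortical_dwell_frames < 1:
        raise ValueError("cortical_dwell_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    p_stop = 1.0 / config.cortical_dwell_frames
    rows = []
    for mt in range(config.n_microtubules):
        pos = _random_interior_point(rng, poly, config.band_um + 1.0)
        # aim at a random point on the boundary
        target = _boundary_point(rng, poly)
        state = "growth"
        dwell_left = 0
        for frame in range(config.n_frames):
            rows.append(
                (f"mt{mt:04d}", frame, frame * config.frame_interval_s, pos[0], pos[1], state)
            )
            if state == "paused":
                dwell_left -= 1
                if dwell_left <= 0:
                    pos = _random_interior_point(rng, poly, config.band_um + 1.0)
                    target = _boundary_point(rng, poly)
                    state = "growth"
                continue
            # growth: catastrophe or advance toward the boundary target
            if rng.random() < config.catastrophe_prob:
                pos = _random_interior_point(rng, poly, config.band_um + 1.0)
                target = _boundary_point(rng, poly)
                continue
            direction = target - pos
            dist = np.hypot(*direction)
            step = min(config.growth_speed_um_per_frame, max(dist - 1e-6, 0.0))
            new = pos + (direction / dist) * step if dist > 0 else pos
            if not poly.covers(Point(new)):
                new = np.asarray(
                    poly.exterior.interpolate(poly.exterior.project(Point(new))).coords[0]
                )
            pos = new
            if poly.exterior.distance(Point(pos)) <= config.band_um:
                state = "paused"
                dwell_left = rng.geometric(p_stop)
    return pd.DataFrame(rows, columns=["mt_id", "frame", "t_s", "x_um", "y_um", "state"])


def _boundary_point(rng, poly: Polygon) -> np.ndarray:
    s = rng.uniform(0.0, poly.exterior.length)
    return np.asarray(poly.exterior.interpolate(s).coords[0])


def gen_pattern_image(
    image_size: tuple = (256, 256),
    pixel_size_um: float = 0.2,
    patch_diameter_um: float = 2.0,
    pitch_um: float = 9.0,
    mt_segments=None,
    noise: float = 0.0,
    background: float = 10.0,
    ridge_intensity: float = 100.0,
    seed: int = 0,
):
    """Render a micropattern field of view: a square lattice of ligand
    patches (2 um diameter, 9 um pitch) and microtubule polylines drawn as
    bright ridges over additive Gaussian noise.

    Returns (image, centres_um) where centres lie on the 9 um lattice.
    """
    if pitch_um <= patch_diameter_um:
        raise ValueError("pitch must exceed the patch diameter")
    if patch_diameter_um / pixel_size_um < 2.0:
        raise ValueError("pixel size too coarse to resolve the patch")
    from skimage.draw import line as draw_line

    rng = np.random.default_rng(seed)
    h, w = image_size
    img = np.full((h, w), float(background))
    extent_x, extent_y = w * pixel_size_um, h * pixel_size_um
    centres = [
        (x, y)
        for x in np.arange(pitch_um / 2, extent_x, pitch_um)
        for y in np.arange(pitch_um / 2, extent_y, pitch_um)
    ]
    for seg in mt_segments or []:
        pts = np.asarray(seg, dtype=float) / pixel_size_um
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[keep], cc[keep]] = background + ridge_intensity
    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    return img, np.asarray(centres)
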
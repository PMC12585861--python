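"""Synthetic helico-spiral cochleae, trees and traits with known ground truth.

The cochlear canal is modelled as a logarithmic helico-spiral

    x = r(th) cos th,  y = r(th) sin th,  z = c th,   r(th) = a e^{-b th},

with ``th`` running over ``[0, 2 pi N]`` for ``N`` revolutions. ``b = 0``
gives a cylindrical cochlea, larger ``b`` an increasingly conical one; the
closed-form arc length of this curve serves as an oracle for the length and
turn-count metrics. Trees are pure-birth (Yule) and traits evolve on them
under Brownian motion or its standard transforms (EB, OU, Pagel's lambda).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .io_formats import LandmarkConfiguration, Phylogeny

__all__ = [
    "SpiralParams",
    "SimTraits",
    "generate_cochlea",
    "generate_tree",
    "simulate_traits",
    "analytic_arc_length",
]


@dataclass
class SpiralParams:
    """Ground-truth parameters of one synthetic cochlea.

    n_turns
        Revolutions ``N`` of the spiral (> 0). Primate-like cochleae span
        roughly 1.5-4.5 turns.
    basal_radius
        Radius ``a`` at the round window, in length units (mm).
    taper
        Exponential radius decay ``b`` per radian; 0 is cylindrical, values
        around 0.1-0.3 conical.
    pitch
        Axial rise ``c`` per radian.
    n_points
        Number of sampled landmarks along the curve (>= 50).
    noise_sd
        Isotropic Gaussian digitization noise, same units as ``a``.
    """

    n_turns: float = 2.5
    basal_radius: float = 1.0
    taper: float = 0.1
    pitch: float = 0.08
    n_points: int = 200
    noise_sd: float = 0.0
    chirality: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_turns <= 0:
            raise ValueError("n_turns must be > 0")
        if self.basal_radius <= 0:
            raise ValueError("basal_radius must be > 0")
        if self.taper < 0 or self.pitch < 0 or self.noise_sd < 0:
            raise ValueError("taper, pitch and noise_sd must be >= 0")
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.chirality not in ("left", "right"):
            raise ValueError("chirality must be 'left' or 'right'")


@dataclass
class SimTraits:
    """Specification of a trait-evolution simulation.

    ``model`` is one of BM, EB, OU, lambda; ``params`` carries the model's
    parameters: ``sigma2`` (BM rate, > 0) plus ``r`` (EB rate change, <= 0
    typical), ``alpha`` (OU pull, >= 0) or ``lam`` (Pagel's lambda in [0,1]).
    """

    model: str = "BM"
    params: dict = field(default_factory=lambda: {"sigma2": 1.0})
    root: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("BM", "EB", "OU", "lambda"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.params.get("sigma2", 1.0) <= 0:
            raise ValueError("sigma2 must be > 0")
        lam = self.params.get("lam", 1.0)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.params.get("alpha", 0.0) < 0:
            raise ValueError("alpha must be >= 0")


def _spiral_xyz(theta: np.ndarray, p: SpiralParams) -> np.ndarray:
    r = p.basal_radius * np.exp(-p.taper * theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), p.pitch * theta])
    if p.chirality == "left":
        pts[:, 0] = -pts[:, 0]  # mirror of the right-handed curve
    return pts


def generate_cochlea(p: SpiralParams) -> LandmarkConfiguration:
    """Sample a noisy helico-spiral landmark curve with known ground truth.

    Points are sampled at angles uniform on ``[0, 2 pi N]``. Three fixed
    landmarks mark the base, the end of the first turn (point nearest one
    full revolution) and the apex; all other points are semi-landmarks. The
    noiseless curve is attached as ``source_curve`` for necklace sliding.
    A left-chirality curve is exactly the mirror image (x negated) of the
    right-chirality curve drawn with the same seed.
    """
    theta = np.linspace(0.0, 2.0 * np.pi * p.n_turns, p.n_points)
    clean = _spiral_xyz(theta, p)
    rng = np.random.default_rng(p.seed)
    noise = rng.normal(scale=p.noise_sd, size=clean.shape) if p.noise_sd > 0 else 0.0
    pts = clean + noise
    if p.chirality == "left" and p.noise_sd > 0:
        # keep left == mirror(right) exact: mirror the noisy right-hand curve
        right = _spiral_xyz(theta, SpiralParams(**{**p.__dict__, "chirality": "right"}))
        pts = right + noise
        pts[:, 0] = -pts[:, 0]
    fixed = {0, p.n_points - 1}
    if p.n_turns > 1:
        fixed.add(int(np.argmin(np.abs(theta - 2.0 * np.pi))))
    return LandmarkConfiguration(
        specimen_id=f"sim_{p.seed}",
        species_id=f"sim_{p.seed}",
        side=p.chirality,
        points=pts,
        fixed_index_set=frozenset(fixed),
        semi_index_set=frozenset(range(p.n_points)) - frozenset(fixed),
        source_curve=clean,
    )


def analytic_arc_length(p: SpiralParams) -> float:
    """Closed-form arc length of the noiseless spiral, for use as an oracle."""
    a, b, c = p.basal_radius, p.taper, p.pitch

    def speed(th: float) -> float:
        r = a * np.exp(-b * th)
        return float(np.sqrt((b * r) ** 2 + r**2 + c**2))

    total, _ = quad(speed, 0.0, 2.0 * np.pi * p.n_turns, limit=200)
    return total


def generate_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """A pure-birth (Yule) tree on ``n_tips`` tips, rescaled to depth 1.

    The crown split sits at the root; waiting times between speciations are
    exponential with rate equal to the number of extant lineages, and after
    the n-th lineage appears the tree grows for one further exponential
    waiting time (memoryless stopping), so no branch has zero length.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = random.Random(seed)
    t = 0.0
    root = {"birth": 0.0, "children": [], "split": 0.0}
    c1 = {"birth": 0.0, "children": []}
    c2 = {"birth": 0.0, "children": []}
    root["children"] = [c1, c2]
    active = [c1, c2]
    while len(active) < n_tips:
        k = len(active)
        t += rng.expovariate(k)
        node = active.pop(rng.randrange(k))
        node["split"] = t
        a = {"birth": t, "children": []}
        b = {"birth": t, "children": []}
        node["children"] = [a, b]
        active.extend([a, b])
    t += rng.expovariate(len(active))
    total = t

    parent: list[int] = []
    length: list[float] = []
    labels: list[str | None] = []
    tip_counter = [0]

    def visit(node, parent_idx):
        idx = len(parent)
        parent.append(parent_idx)
        if parent_idx == -1:
            length.append(0.0)
        else:
            end = node.get("split", total)
            length.append((end - node["birth"]) / total)
        if node["children"]:
            labels.append(None)
            for ch in node["children"]:
                visit(ch, idx)
        else:
            tip_counter[0] += 1
            labels.append(f"t{tip_counter[0]}")

    visit(root, -1)
    tree = Phylogeny(parent, length, labels)
    # wash out floating noise so the tree is exactly ultrametric at depth 1
    lengths = tree.length.copy()
    d = tree.node_depths()
    for i in tree.tip_indices:
        lengths[i] += 1.0 - d[i]
    return tree.with_lengths(lengths)


def simulate_traits(
    tree: Phylogeny, spec: SimTraits, dims: int = 1
) -> "pd.DataFrame":
    """Simulate tip traits under the requested model, independent across dims.

    Tip values are drawn from N(root * 1, sigma2 * C_model) where C_model is
    the Brownian covariance of the tree transformed according to the model
    (see :func:`spiralshape.evo_models.transform_covariance`).
    """
    import pandas as pd

    from .evo_models import transform_covariance
    from .phylo_stats import phylo_cov

    if dims < 1:
        raise ValueError("dims must be >= 1")
    C = phylo_cov(tree)
    model_params = {k: v for k, v in spec.params.items() if k != "sigma2"}
    Cm = transform_covariance(tree, spec.model, model_params, C=C)
    sigma2 = spec.params.get("sigma2", 1.0)
    V = sigma2 * Cm
    # eigen square root: robust to the singular limits (lambda=0, sigma2->0)
    w, U = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    L = U * np.sqrt(w)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((tree.tip_count, dims))
    values = spec.root + L @ z
    cols = [f"trait_{j + 1}" for j in range(dims)]
    df = pd.DataFrame(values, index=pd.Index(tree.tip_labels, name="species_id"), columns=cols)
    return df
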
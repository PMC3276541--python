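"""Generators for all network variants used in the PING breakdown studies.

This is the package's synthetic-data layer. It produces:

* homogeneous all-to-all E/I networks,
* sparse random networks with strength compensation (surviving synapses are
  scaled by 1/p so the population-mean conductance per target cell is
  preserved exactly in expectation),
* heterogeneous tonic drive vectors ("h % heterogeneity": drives evenly
  spaced on [Ī(1−h/100), Ī(1+h/100)], randomly assigned to cells),
* independent Poisson schedules of excitatory input pulses per E-cell
  (the kainate-background analogue), and
* spatially structured networks on the unit disk in which the *probability*
  (not the strength) of a connection decays exponentially with distance.

Conductance-density notation follows the field's convention: lower-case g is
the per-pair synaptic conductance density, G its sum over presynaptic cells
(one value per postsynaptic target), and Ḡ the average of G over targets.
Matrices are indexed [presynaptic, postsynaptic].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "DriveSpec",
    "SpatialLayout",
    "build_all_to_all",
    "build_random_network",
    "make_heterogeneous_drives",
    "make_poisson_drive",
    "build_spatial_network",
    "select_driven_patch",
]


@dataclass
class NetworkSpec:
    """Connectivity of an E/I network as conductance-density matrices.

    ``g_ei[i, j]`` is the maximal conductance density (mS/cm²) of the synapse
    from E-cell i onto I-cell j, and similarly for ``g_ie``, ``g_ii`` and the
    (usually absent) ``g_ee``.
    """

    n_e: int
    n_i: int
    g_ei: np.ndarray  # (n_e, n_i)
    g_ie: np.ndarray  # (n_i, n_e)
    g_ii: np.ndarray  # (n_i, n_i)
    g_ee: np.ndarray | None = None  # (n_e, n_e), default absent
    seed: int | None = None

    def __post_init__(self) -> None:
        self.g_ei = np.asarray(self.g_ei, dtype=float)
        self.g_ie = np.asarray(self.g_ie, dtype=float)
        self.g_ii = np.asarray(self.g_ii, dtype=float)
        shapes = {"g_ei": (self.n_e, self.n_i), "g_ie": (self.n_i, self.n_e),
                  "g_ii": (self.n_i, self.n_i)}
        for name, shape in shapes.items():
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {mat.shape}")
            if np.any(mat < 0):
                raise ValueError(f"{name} has negative conductance entries")
        if self.g_ee is not None:
            self.g_ee = np.asarray(self.g_ee, dtype=float)
            if self.g_ee.shape != (self.n_e, self.n_e):
                raise ValueError("g_ee has wrong shape")

    # Per-target presynaptic sums G and their population means Ḡ.
    def G(self, projection: str) -> np.ndarray:
        """Summed conductance density per postsynaptic target (row totals)."""
        mat = getattr(self, "g_" + projection.lower())
        if mat is None:
            raise ValueError(f"projection {projection} absent")
        return mat.sum(axis=0)

    def Gbar(self, projection: str) -> float:
        """Population mean of G over postsynaptic cells."""
        return float(self.G(projection).mean())

    def to_json(self) -> str:
        payload = {
            "n_e": self.n_e, "n_i": self.n_i, "seed": self.seed,
            "g_ei": self.g_ei.tolist(), "g_ie": self.g_ie.tolist(),
            "g_ii": self.g_ii.tolist(),
            "g_ee": None if self.g_ee is None else self.g_ee.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(n_e=d["n_e"], n_i=d["n_i"], g_ei=np.array(d["g_ei"]),
                   g_ie=np.array(d["g_ie"]), g_ii=np.array(d["g_ii"]),
                   g_ee=None if d["g_ee"] is None else np.array(d["g_ee"]),
                   seed=d["seed"])


@dataclass
class DriveSpec:
    """External drive to every cell: tonic current densities plus an optional
    Poisson background of excitatory input pulses to the E-cells.

    ``poisson_rate`` (Hz) and ``poisson_g`` (mS/cm², conductance added per
    event) describe the stochastic kainate-analogue background; each event
    adds ``poisson_g`` to an input gate that decays with ``poisson_tau`` ms.
    ``driven_idx`` lists the E-cells receiving the strong tonic drive.
    """

    drive_e: np.ndarray
    drive_i: np.ndarray
    heterogeneity_pct: float = 0.0
    poisson_rate: float = 0.0
    poisson_g: float = 0.0
    poisson_tau: float = 3.0
    driven_idx: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.drive_e = np.atleast_1d(np.asarray(self.drive_e, dtype=float))
        self.drive_i = np.atleast_1d(np.asarray(self.drive_i, dtype=float))
        if not (np.all(np.isfinite(self.drive_e)) and np.all(np.isfinite(self.drive_i))):
            raise ValueError("drives must be finite")
        if self.poisson_rate < 0:
            raise ValueError("Poisson rate must be non-negative")
        if self.driven_idx is not None:
            self.driven_idx = np.asarray(self.driven_idx, dtype=int)
            if self.driven_idx.size > self.drive_e.size:
                raise ValueError("more driven cells than E-cells")

    def to_json(self) -> str:
        return json.dumps({
            "drive_e": self.drive_e.tolist(), "drive_i": self.drive_i.tolist(),
            "heterogeneity_pct": self.heterogeneity_pct,
            "poisson_rate": self.poisson_rate, "poisson_g": self.poisson_g,
            "poisson_tau": self.poisson_tau,
            "driven_idx": None if self.driven_idx is None else self.driven_idx.tolist(),
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "DriveSpec":
        d = json.loads(text)
        idx = d.pop("driven_idx")
        return cls(drive_e=np.array(d.pop("drive_e")), drive_i=np.array(d.pop("drive_i")),
                   driven_idx=None if idx is None else np.array(idx, dtype=int), **d)


@dataclass
class SpatialLayout:
    """Random cell positions in the unit disk, with the driven-patch radius ρ
    and the connection-probability length constant ℓ (both dimensionless /
    in units of the disk radius)."""

    pos_e: np.ndarray  # (n_e, 2)
    pos_i: np.ndarray  # (n_i, 2)
    rho: float = 1.0
    ell: float = 0.25

    def __post_init__(self) -> None:
        self.pos_e = np.asarray(self.pos_e, dtype=float)
        self.pos_i = np.asarray(self.pos_i, dtype=float)
        for pos in (self.pos_e, self.pos_i):
            if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-12):
                raise ValueError("positions must lie in the unit disk")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must lie in (0, 1]")
        if self.ell <= 0:
            raise ValueError("ell must be positive")


def _uniform_matrix(n_pre: int, n_post: int, gbar: float, *, exclude_self: bool) -> np.ndarray:
    """All-to-all matrix whose per-target sum G equals gbar exactly."""
    denom = n_pre - 1 if exclude_self else n_pre
    if denom <= 0:
        return np.zeros((n_pre, n_post))
    g = np.full((n_pre, n_post), gbar / denom)
    if exclude_self:
        np.fill_diagonal(g, 0.0)
    return g


def build_all_to_all(n_e: int, n_i: int, gbar_ei: float, gbar_ie: float,
                     gbar_ii: float, include_ii: bool = True,
                     seed: int | None = None) -> NetworkSpec:
    """Homogeneous all-to-all network: every row sum G equals Ḡ exactly."""
    return NetworkSpec(
        n_e=n_e, n_i=n_i,
        g_ei=_uniform_matrix(n_e, n_i, gbar_ei, exclude_self=False),
        g_ie=_uniform_matrix(n_i, n_e, gbar_ie, exclude_self=False),
        g_ii=_uniform_matrix(n_i, n_i, gbar_ii if include_ii else 0.0, exclude_self=True),
        seed=seed,
    )


def _sparsify(dense: np.ndarray, p: float, rng, *, exclude_self: bool) -> np.ndarray:
    """Bernoulli(p) mask with 1/p compensation, preserving Ḡ in expectation."""
    if p == 1.0:
        return dense.copy()
    mask = rng.random(dense.shape) < p
    if exclude_self:
        np.fill_diagonal(mask, False)
    return np.where(mask, dense / p, 0.0)


def build_random_network(n_e: int, n_i: int, p, gbar_ei: float, gbar_ie: float,
                         gbar_ii: float, include_ii: bool = True,
                         seed: int | None = None) -> NetworkSpec:
    """Sparse random network with strength compensation.

    Each potential connection exists independently with probability ``p``
    (scalar, or a dict with keys ``'ei'``, ``'ie'``, ``'ii'`` for
    per-projection probabilities); surviving synapses are scaled by 1/p so
    the population-mean conductance per target equals the requested Ḡ in
    expectation — e.g. at 50 % connectivity the survivors are doubled in
    strength.
    """
    if isinstance(p, dict):
        p_ei, p_ie, p_ii = p.get("ei", 1.0), p.get("ie", 1.0), p.get("ii", 1.0)
    else:
        p_ei = p_ie = p_ii = float(p)
    for pv, gbar in ((p_ei, gbar_ei), (p_ie, gbar_ie), (p_ii, gbar_ii)):
        if not (0.0 <= pv <= 1.0):
            raise ValueError("connection probability must lie in [0, 1]")
        if pv == 0.0 and gbar > 0.0:
            raise ValueError("p = 0 with a nonzero target mean conductance")
    rng = np.random.default_rng(seed)
    dense = build_all_to_all(n_e, n_i, gbar_ei, gbar_ie, gbar_ii,
                             include_ii=include_ii)
    return NetworkSpec(
        n_e=n_e, n_i=n_i,
        g_ei=_sparsify(dense.g_ei, p_ei, rng, exclude_self=False),
        g_ie=_sparsify(dense.g_ie, p_ie, rng, exclude_self=False),
        g_ii=_sparsify(dense.g_ii, p_ii, rng, exclude_self=True),
        seed=seed,
    )


def make_heterogeneous_drives(n: int, mean: float, h: float,
                              seed: int | None = None) -> np.ndarray:
    """Tonic drives with "h % heterogeneity".

    Values are evenly spaced on [mean·(1 − h/100), mean·(1 + h/100)] and
    randomly assigned to cells, so the sample mean equals ``mean`` exactly
    and the max-min spread is 2·(h/100)·mean. ``h = 0`` returns identical
    drives.
    """
    if h < 0:
        raise ValueError("heterogeneity percentage must be non-negative")
    if mean < 0:
        raise ValueError("mean drive must be non-negative")
    if n == 1 or h == 0.0:
        return np.full(n, mean)
    spread = mean * h / 100.0
    drives = np.linspace(mean - spread, mean + spread, n)
    rng = np.random.default_rng(seed)
    return rng.permutation(drives)


def make_poisson_drive(n_e: int, rate: float, t_max: float,
                       seed: int | None = None) -> list[np.ndarray]:
    """Independent Poisson event schedules, one per E-cell.

    ``rate`` is the event rate in Hz; ``t_max`` the schedule horizon in ms.
    Returns a list of sorted event-time arrays (ms).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    schedules: list[np.ndarray] = []
    rate_per_ms = rate / 1000.0
    for _ in range(n_e):
        if rate_per_ms == 0.0:
            schedules.append(np.empty(0))
            continue
        n_ev = rng.poisson(rate_per_ms * t_max)
        schedules.append(np.sort(rng.uniform(0.0, t_max, size=n_ev)))
    return schedules


def random_disk_positions(n: int, rng) -> np.ndarray:
    """Uniform random points in the unit disk."""
    r = np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])


def build_spatial_network(n_e: int, n_i: int, ell: float,
                          g_syn_ei: float, g_syn_ie: float, g_syn_ii: float,
                          rho: float = 1.0,
                          seed: int | None = None) -> tuple[NetworkSpec, SpatialLayout]:
    """Spatially structured network on the unit disk.

    Cells are placed uniformly at random; each directed connection is drawn
    independently with probability exp(−d/ℓ), d the Euclidean distance
    between the cells. Synaptic *strengths* are uniform (``g_syn_xy`` per
    existing synapse): locality is expressed purely through the connection
    probability. Self-connections are excluded.
    """
    if ell <= 0:
        raise ValueError("ell must be positive")
    rng = np.random.default_rng(seed)
    pos_e = random_disk_positions(n_e, rng)
    pos_i = random_disk_positions(n_i, rng)

    def draw(pre, post, g_syn, exclude_self):
        d = _distance_matrix(pre, post)
        mask = rng.random(d.shape) < np.exp(-d / ell)
        if exclude_self:
            np.fill_diagonal(mask, False)
        return np.where(mask, g_syn, 0.0)

    net = NetworkSpec(
        n_e=n_e, n_i=n_i,
        g_ei=draw(pos_e, pos_i, g_syn_ei, False),
        g_ie=draw(pos_i, pos_e, g_syn_ie, False),
        g_ii=draw(pos_i, pos_i, g_syn_ii, True),
        seed=seed,
    )
    return net, SpatialLayout(pos_e=pos_e, pos_i=pos_i, rho=rho, ell=ell)


def select_driven_patch(layout: SpatialLayout, rho: float | None = None) -> np.ndarray:
    """Indices of E-cells within distance ρ of the disk center."""
    rho = layout.rho if rho is None else rho
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must lie in (0, 1]")
    r = np.hypot(layout.pos_e[:, 0], layout.pos_e[:, 1])
    return np.nonzero(r <= rho)[0]
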
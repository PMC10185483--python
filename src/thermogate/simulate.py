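"""Seeded synthetic gating datasets with the model's own statistical structure.

Each simulated record draws ``n_open ~ Binomial(n_trials, P_open(T))`` (or the
polymodal curve when a voltage is given), emulating patch-clamp-style open
probability estimates on a temperature grid. An ``exact`` noise mode rounds
``n_trials * p`` instead, producing noise-free proportions for round-trip
tests. Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import model
from .constants import R
from .data import PopenDataset
from .model import GatingParams

__all__ = ["SimulationConfig", "simulate_dataset", "make_fixture_suite"]


@dataclass(frozen=True)
class SimulationConfig:
    """Recipe for one synthetic dataset.

    Attributes
    ----------
    true_params : GatingParams
        Ground-truth thermodynamic parameters.
    T_grid : ndarray
        Strictly increasing temperatures, kelvin.
    n_trials : int or ndarray
        Trials per grid point (scalar broadcast, or one value per point).
        A "trial" abstracts one independent open/closed observation
        (sweep, or channel x sweep); the equilibrium model treats openings
        as exchangeable.
    V : float or ndarray or None
        Optional holding voltage, volts; requires voltage-capable params.
    noise : str
        ``"binomial"`` (sampling noise) or ``"exact"`` (round-half-to-even
        of n*p).
    seed : int
        Seed for the binomial draws.
    label : str
        Carried into the dataset for provenance.
    """

    true_params: GatingParams
    T_grid: np.ndarray
    n_trials: int | np.ndarray = 100
    V: float | np.ndarray | None = None
    noise: str = "binomial"
    seed: int = 0
    label: str = "simulated"

    def __post_init__(self) -> None:
        T = np.asarray(self.T_grid, dtype=float)
        if T.ndim != 1 or T.size < 1:
            raise ValueError("T_grid must be a non-empty 1-d array")
        if np.any(T <= 0):
            raise ValueError("all grid temperatures must be positive (kelvin)")
        if np.any(np.diff(T) <= 0):
            raise ValueError("T_grid must be strictly increasing")
        n = np.broadcast_to(np.asarray(self.n_trials, dtype=int), T.shape).copy()
        if np.any(n < 1):
            raise ValueError("n_trials must be >= 1 everywhere")
        if self.noise not in ("binomial", "exact"):
            raise ValueError(f"noise must be 'binomial' or 'exact', got {self.noise!r}")
        if self.V is not None and not self.true_params.has_voltage:
            raise ValueError("a voltage covariate requires params with z and V_half")
        object.__setattr__(self, "T_grid", T)
        object.__setattr__(self, "n_trials", n)

    @classmethod
    def from_range(
        cls,
        true_params: GatingParams,
        T_min: float,
        T_max: float,
        n_points: int,
        **kwargs,
    ) -> "SimulationConfig":
        """Build the grid from an inclusive range instead of explicit points."""
        return cls(true_params, np.linspace(T_min, T_max, n_points), **kwargs)


def simulate_dataset(config: SimulationConfig) -> PopenDataset:
    """Draw one dataset from the two-state truth model.

    Binomial noise uses ``numpy.random.default_rng(config.seed)``, so two
    calls with identical configs produce identical records.
    """
    T = config.T_grid
    if config.V is not None:
        V = np.broadcast_to(np.asarray(config.V, dtype=float), T.shape)
        p = np.asarray(model.joint_open_probability(config.true_params, T, V))
    else:
        V = None
        p = np.asarray(model.open_probability(config.true_params, T))
    if config.noise == "binomial":
        rng = np.random.default_rng(config.seed)
        n_open = rng.binomial(config.n_trials, p)
    else:  # exact: numpy rounds half to even
        n_open = np.rint(config.n_trials * p).astype(int)
    return PopenDataset(
        T=T, n_trials=config.n_trials, n_open=n_open, V=V, label=config.label
    )


# Standard fixture battery. Grids bracket each midpoint by >= 1.5 linear-rise
# widths (width ~10 K at 125R) so both plateaus are sampled.
def _fixture_configs(seed: int) -> dict[str, SimulationConfig]:
    trpv1 = GatingParams(delta_S=125.0 * R, T_half=316.0)
    trpm8 = GatingParams(delta_S=-125.0 * R, T_half=299.0)
    return {
        "trpv1_like": SimulationConfig(
            trpv1, np.arange(298.0, 329.0), n_trials=500, seed=seed, label="trpv1_like"
        ),
        "trpm8_like": SimulationConfig(
            trpm8, np.arange(283.0, 314.0), n_trials=500, seed=seed + 1, label="trpm8_like"
        ),
        "low_n_noisy": SimulationConfig(
            trpv1, np.arange(298.0, 329.0, 2.0), n_trials=20, seed=seed + 2, label="low_n_noisy"
        ),
        # Grid entirely below threshold: every draw lands closed.
        "all_closed": SimulationConfig(
            trpv1, np.arange(273.0, 284.0), n_trials=50, noise="exact",
            seed=seed + 3, label="all_closed",
        ),
    }


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the standard fixture battery and return its manifest.

    Produces four CSVs in the inference input schema — a TRPV1-like type-I
    hyperthermic set, a TRPM8-like type-II hypothermic set, a low-count noisy
    set, and a degenerate all-closed set — plus ``manifest.json`` recording
    the truth parameters, configs and SHA-256 checksums. Regeneration with
    the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}
    for name, config in _fixture_configs(seed).items():
        data = simulate_dataset(config)
        path = out_dir / f"{name}.csv"
        data.to_csv(path)
        manifest["files"][name] = {
            "path": path.name,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "truth": {
                "delta_S_in_R": config.true_params.delta_S_in_R,
                "T_half_K": config.true_params.T_half,
            },
            "n_trials": int(np.max(config.n_trials)),
            "noise": config.noise,
            "seed": config.seed,
            "T_min_K": float(config.T_grid[0]),
            "T_max_K": float(config.T_grid[-1]),
            "n_points": int(config.T_grid.size),
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
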
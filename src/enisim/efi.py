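"""Electrical field imaging: lumped resistor ladder networks.

An EFI measurement stimulates one intracochlear electrode at a time and
records the voltage on all electrodes; scaling by the injected current gives
an n x n resistance matrix (Ohms).  The standard physical summary of such a
matrix is a ladder network: each electrode node couples to the distant ground
through a transversal resistance ``r_trans[i]`` and to its neighbours along
the cochlear duct through longitudinal resistances ``r_long[i]`` (between
nodes ``i`` and ``i+1``).  This module provides

* :func:`forward_efi` — nodal solve of the ladder, producing the model
  resistance matrix for unit injections at every electrode;
* :func:`solve_network` — weighted least-squares inversion of a measured
  matrix back to the ladder parameters (in log space, so positivity is
  guaranteed by construction);
* :func:`r_total` — the per-electrode peak of the reconstructed profile;
* :func:`log_resistance` — the base-10 log transform applied before
  statistical analysis.

Diagonal entries of a real EFI matrix contain electrode-contact polarization
impedance that the purely resistive ladder does not model; whether they
enter the fit objective is a documented switch on :func:`solve_network`.
Either way the reconstructed (model) diagonal is what ``r_total`` reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LadderNetwork",
    "EFIMatrix",
    "FitDiagnostics",
    "forward_efi",
    "solve_network",
    "r_total",
    "log_resistance",
    "average_pulse_matrices",
    "write_efi_csv",
    "read_efi_csv",
]


@dataclasses.dataclass
class LadderNetwork:
    """Transversal/longitudinal parameter set of an n-electrode ladder.

    ``r_trans`` has one node-to-ground resistance per electrode (length n);
    ``r_long`` has one node-to-node resistance per adjacent pair (length n-1).
    All resistances are strictly positive Ohms.
    """

    r_trans: np.ndarray
    r_long: np.ndarray

    def __post_init__(self) -> None:
        self.r_trans = np.asarray(self.r_trans, dtype=float)
        self.r_long = np.asarray(self.r_long, dtype=float)
        if self.r_trans.ndim != 1 or self.r_long.ndim != 1:
            raise ValueError("r_trans and r_long must be 1-D arrays")
        if len(self.r_long) != len(self.r_trans) - 1:
            raise ValueError(
                f"r_long must have length n-1={len(self.r_trans) - 1}, "
                f"got {len(self.r_long)}"
            )
        if not np.all(np.isfinite(self.r_trans)) or np.any(self.r_trans <= 0):
            raise ValueError("r_trans: all resistances must be finite and > 0")
        if not np.all(np.isfinite(self.r_long)) or np.any(self.r_long <= 0):
            raise ValueError("r_long: all resistances must be finite and > 0")

    @property
    def n(self) -> int:
        return len(self.r_trans)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"r_trans": self.r_trans.tolist(), "r_long": self.r_long.tolist()},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LadderNetwork":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["r_trans"]), np.asarray(d["r_long"]))


@dataclasses.dataclass
class EFIMatrix:
    """Stimulation-by-recording resistance matrix in Ohms.

    ``z[i, j]`` is the voltage on recording electrode i per unit current
    injected on stimulating electrode j.  ``valid`` masks entries that may
    enter a fit (open or broken contacts can be masked out).
    """

    z: np.ndarray
    current_ua: float = 1.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be a square matrix")
        if self.valid is None:
            self.valid = np.isfinite(self.z)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.z.shape:
                raise ValueError("valid mask must match z shape")

    @property
    def n(self) -> int:
        return self.z.shape[0]


@dataclasses.dataclass
class FitDiagnostics:
    converged: bool
    weighted_residual: float
    n_iterations: int
    message: str


def _conductance_matrix(network: LadderNetwork) -> np.ndarray:
    n = network.n
    gt = 1.0 / network.r_trans
    gl = 1.0 / network.r_long
    G = np.zeros((n, n))
    G[np.arange(n), np.arange(n)] = gt
    G[np.arange(n - 1), np.arange(n - 1)] += gl
    G[np.arange(1, n), np.arange(1, n)] += gl
    G[np.arange(n - 1), np.arange(1, n)] -= gl
    G[np.arange(1, n), np.arange(n - 1)] -= gl
    return G


def forward_efi(network: LadderNetwork, current_ua: float = 1.0) -> EFIMatrix:
    """Solve the ladder for injections at every node.

    Column j holds the node voltages per unit current injected at node j with
    an extracochlear ground return; by reciprocity the matrix is symmetric,
    and columns decay monotonically away from the diagonal.
    """
    if network.n < 2:
        raise ValueError("forward model needs at least 2 electrodes")
    if current_ua <= 0:
        raise ValueError("current_ua must be > 0")
    G = _conductance_matrix(network)
    # z[:, j] = G^{-1} e_j  (resistance units: V per A == Ohms)
    z = np.linalg.solve(G, np.eye(network.n))
    z = 0.5 * (z + z.T)  # enforce exact symmetry against round-off
    return EFIMatrix(z=z, current_ua=current_ua)


def r_total(network: LadderNetwork) -> np.ndarray:
    """Per-electrode total resistance: the peak of the reconstructed profile.

    For a ladder the reconstructed column peaks on the diagonal, so this is
    the diagonal of the forward-modelled matrix.
    """
    return np.diag(forward_efi(network).z).copy()


def log_resistance(values) -> np.ndarray:
    """Base-10 log transform used before statistical analysis."""
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("log_resistance requires positive finite values")
    return np.log10(v)


def _initial_guess(z: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = z.shape[0]
    diag = np.diag(z)[np.diag(valid)]
    rt0 = float(np.median(diag)) if diag.size else 1.0
    adj = []
    for i in range(n - 1):
        if valid[i, i] and valid[i, i + 1]:
            adj.append(z[i, i] - z[i, i + 1])
    rl0 = float(np.median(adj)) if adj else rt0 / 2.0
    rt0 = max(rt0, 1e-6)
    rl0 = max(rl0, 1e-6)
    return np.full(n, rt0), np.full(n - 1, rl0)


def solve_network(
    efi: EFIMatrix,
    weighting_tau: float = 3.0,
    include_diagonal: bool = True,
    max_iterations: int = 500,
) -> tuple[LadderNetwork, FitDiagnostics]:
    """Invert a measured resistance matrix to ladder parameters.

    Minimizes sum over valid entries of ``w(i,j) * (z_model - z)**2`` with
    the localized weighting ``w = exp(-|i-j| / tau)``, over log-resistances
    (positivity by construction).

    ``include_diagonal`` controls whether the profile peaks enter the
    objective.  Excluding them discards the electrode-contact polarization
    that a purely resistive ladder cannot represent, but it also leaves one
    exactly flat direction in the objective at each end of the array (the
    end transversal/longitudinal triplet is then only identified up to a
    one-parameter family), so the default keeps the diagonal; set it to
    False for matrices whose diagonals carry substantial contact impedance.
    """
    n = efi.n
    if n < 3:
        raise ValueError("inversion needs at least 3 electrodes")
    mask = efi.valid.copy()
    if not include_diagonal:
        mask &= ~np.eye(n, dtype=bool)
    if not mask.any():
        raise ValueError("all fit entries are masked; nothing to fit")
    ii, jj = np.nonzero(mask)
    w = np.exp(-np.abs(ii - jj) / float(weighting_tau))
    sqrt_w = np.sqrt(w)
    zobs = efi.z[ii, jj]

    rt0, rl0 = _initial_guess(efi.z, mask | np.eye(n, dtype=bool))
    theta0 = np.log(np.concatenate([rt0, rl0]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        # clip so optimizer trial steps cannot overflow exp
        theta = np.clip(theta, np.log(1e-9), np.log(1e12))
        net = LadderNetwork(np.exp(theta[:n]), np.exp(theta[n:]))
        zm = forward_efi(net).z
        return sqrt_w * (zm[ii, jj] - zobs)

    res = least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iterations * (len(theta0) + 1),
    )
    x = np.clip(res.x, np.log(1e-9), np.log(1e12))
    network = LadderNetwork(np.exp(x[:n]), np.exp(x[n:]))
    diag = FitDiagnostics(
        converged=bool(res.status > 0),
        weighted_residual=float(2.0 * res.cost),
        n_iterations=int(res.nfev),
        message=str(res.message),
    )
    return network, diag


def average_pulse_matrices(matrices) -> np.ndarray:
    """Average a stack of per-pulse resistance matrices (upstream helper)."""
    stack = np.asarray(matrices, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a stack of 2-D matrices")
    return stack.mean(axis=0)


def write_efi_csv(efi: EFIMatrix, path: str | Path) -> None:
    """Plain n x n CSV with a header comment recording the applied current."""
    with open(path, "w") as fh:
        fh.write(f"# current_ua={efi.current_ua}\n")
        np.savetxt(fh, efi.z, delimiter=",", fmt="%.10g")


def read_efi_csv(path: str | Path) -> EFIMatrix:
    current = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("current_ua="):
                    current = float(token.split("=", 1)[1])
            z = np.loadtxt(fh, delimiter=",")
        else:
            fh.seek(0)
            z = np.loadtxt(fh, delimiter=",")
    return EFIMatrix(z=z, current_ua=current)
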
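"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without instrument or
simulation data:

* near-UV conjugate/parent spectrum pairs — a bisignate Gaussian exciton
  couplet (Λ positive lobe at 295 nm, negative at 270 nm, amplitude 114
  M⁻¹cm⁻¹ for the enantiopure reference) mixed at known enantiomer fractions,
  scaled by a partial labeling ratio, superposed on a broad low-amplitude
  host-protein baseline, with additive Gaussian noise;
* bound/free reaction pairs that conserve chiral amounts from a racemic
  labeling pool (the conjugation reaction uses a molar excess of racemic
  chromophore, so the unreacted fraction is enriched in the opposite
  enantiomer);
* toy trajectories whose per-frame minimum inter-set distance follows a
  prescribed (optionally bimodal) distribution, for the contact-distance
  statistics.

All randomness flows from one explicit integer seed per call; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import Trajectory
from .errors import RangeError, ValidationError
from .spectra import DELTA_EPSILON, Spectrum

LAMBDA_SIGN = "lambda"
DELTA_SIGN = "delta"


@dataclass(frozen=True)
class CoupletModel:
    """Bisignate Gaussian exciton couplet of a tris-chelate chromophore.

    The Λ couplet has a positive lobe at ``center_pos`` and a negative lobe
    at ``center_neg`` (positive-to-negative with decreasing wavelength ⇒
    positive chirality); the Δ couplet is its exact pointwise negation.
    ``amplitude`` is the peak Δε of the enantiopure complex at the positive
    lobe (114 M⁻¹cm⁻¹ for the Λ reference).
    """

    center_pos: float = 295.0      # nm
    center_neg: float = 270.0      # nm
    width: float = 10.0            # Gaussian sigma, nm
    amplitude: float = 114.0       # M⁻¹cm⁻¹
    sign: str = LAMBDA_SIGN

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValidationError("amplitude must be > 0")
        if not self.center_neg < self.center_pos:
            raise ValidationError("lobes must be ordered center_neg < center_pos")
        if self.sign not in (LAMBDA_SIGN, DELTA_SIGN):
            raise ValidationError(f"sign must be {LAMBDA_SIGN!r} or {DELTA_SIGN!r}")
        if not self.width > 0:
            raise ValidationError("width must be > 0")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Couplet Δε on ``grid`` (nm)."""
        grid = np.asarray(grid, dtype=float)
        shape = (np.exp(-0.5 * ((grid - self.center_pos) / self.width) ** 2)
                 - np.exp(-0.5 * ((grid - self.center_neg) / self.width) ** 2))
        out = self.amplitude * shape
        return -out if self.sign == DELTA_SIGN else out

    def spectrum(self, grid) -> Spectrum:
        grid = np.asarray(grid, dtype=float)
        return Spectrum(grid, self.evaluate(grid), DELTA_EPSILON,
                        {"synthetic": "pure couplet", "sign": self.sign})


@dataclass(frozen=True)
class MixtureSpec:
    """Enantiomer mixture, labeling and noise for one synthetic conjugate."""

    frac_lambda: float
    frac_delta: float
    label_ratio: float = 1.0
    host_scale: float = 1.0
    noise_sd: float = 0.0          # M⁻¹cm⁻¹, per grid point
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_lambda <= 1 and 0 <= self.frac_delta <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(self.frac_lambda + self.frac_delta - 1.0) > 1e-12:
            raise ValidationError("fractions must sum to 1")
        if not 0 < self.label_ratio <= 1.0:
            raise ValidationError("label_ratio must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def op_true(self) -> float:
        return self.frac_lambda - self.frac_delta


def host_baseline(grid: np.ndarray, couplet_amplitude: float = 114.0,
                  scale: float = 1.0) -> np.ndarray:
    """Broad low-amplitude host-protein near-UV shoulder (aromatic/heme L band).

    A single Gaussian centered at 285 nm with σ = 25 nm and peak 10% of the
    couplet amplitude — enough structure to make the parent subtraction a
    real operation without modeling heme CD.
    """
    grid = np.asarray(grid, dtype=float)
    return scale * 0.10 * couplet_amplitude * np.exp(-0.5 * ((grid - 285.0) / 25.0) ** 2)


def generate_conjugate_spectrum(model: CoupletModel, mix: MixtureSpec, grid,
                                ) -> tuple[Spectrum, Spectrum, dict]:
    """Synthetic (conjugate, parent) Δε pair plus the generating truth record.

    conjugate = host + label_ratio · (frac_Λ − frac_Δ) · couplet_Λ + noise
    parent    = host + independent noise

    The truth record stores every generating parameter, including the signed
    ``op_true`` that downstream analysis should recover.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid.min(), grid.max()
    if model.center_neg < lo or model.center_pos > hi:
        raise RangeError("grid does not cover both couplet lobes")
    lam = CoupletModel(model.center_pos, model.center_neg, model.width,
                       model.amplitude, LAMBDA_SIGN)
    host = host_baseline(grid, model.amplitude, mix.host_scale)
    rng = np.random.default_rng(mix.seed)
    noise_c = rng.normal(0.0, mix.noise_sd, grid.size) if mix.noise_sd > 0 else 0.0
    noise_p = rng.normal(0.0, mix.noise_sd, grid.size) if mix.noise_sd > 0 else 0.0
    conj_vals = host + mix.label_ratio * mix.op_true * lam.evaluate(grid) + noise_c
    par_vals = host + noise_p
    meta = {"synthetic": "conjugate/parent pair", "seed": mix.seed}
    conjugate = Spectrum(grid, conj_vals, DELTA_EPSILON, meta)
    parent = Spectrum(grid, par_vals, DELTA_EPSILON, meta)
    truth = {
        "op_true": mix.op_true,
        "frac_lambda": mix.frac_lambda,
        "frac_delta": mix.frac_delta,
        "label_ratio": mix.label_ratio,
        "noise_sd": mix.noise_sd,
        "host_scale": mix.host_scale,
        "amplitude": model.amplitude,
        "seed": mix.seed,
    }
    return conjugate, parent, truth


@dataclass(frozen=True)
class ReactionSide:
    """Truth record for one side (bound or free) of a labeling reaction."""

    amount: float                  # relative moles (protein sites = 1)
    op: float
    frac_lambda: float
    frac_delta: float


def generate_reaction_pair(bound_op: float, excess: float = 2.0,
                           bound_amount: float = 1.0,
                           ) -> tuple[ReactionSide, ReactionSide]:
    """Bound/free enantiomer truth records conserving a racemic pool.

    The labeling reaction starts from ``excess`` molar equivalents of racemic
    chromophore per protein; ``bound_amount`` equivalents end up conjugated
    with signed optical purity ``bound_op`` and the remainder stays free.
    Conservation of each enantiomer fixes the free pool's op:

        free_op = − bound_op · bound_amount / free_amount.

    Errors when the requested composition is infeasible for the pool (it
    would require a free-pool |op| > 1 or a negative enantiomer amount).
    """
    if excess < 1:
        raise ValidationError("excess must be >= 1")
    if not 0 < bound_amount <= excess:
        raise ValidationError("bound_amount must lie in (0, excess]")
    if abs(bound_op) > 1:
        raise ValidationError("|bound_op| cannot exceed 1")
    free_amount = excess - bound_amount
    if free_amount == 0:
        if bound_op != 0:
            raise ValidationError(
                "no free pool left: a fully consumed racemic pool cannot "
                "yield a nonzero bound op")
        free_op = 0.0
    else:
        free_op = -bound_op * bound_amount / free_amount
        if abs(free_op) > 1 + 1e-12:
            raise ValidationError(
                f"bound op {bound_op} at amount {bound_amount} infeasible for "
                f"excess {excess}: free pool would need |op| = {abs(free_op):.3f}")
        free_op = float(np.clip(free_op, -1.0, 1.0))
    bound = ReactionSide(bound_amount, bound_op,
                         (1 + bound_op) / 2, (1 - bound_op) / 2)
    free = ReactionSide(free_amount, free_op,
                        (1 + free_op) / 2, (1 - free_op) / 2)
    return bound, free


def generate_trajectory(n_frames: int, n_atoms_a: int, n_atoms_b: int,
                        target_mean: float, target_sd: float,
                        modes: int = 1, mode_separation: float = 5.0,
                        seed: int = 0, frame_dt: float = 10.0,
                        ) -> tuple[Trajectory, dict]:
    """Toy trajectory whose per-frame minimum A–B distance is prescribed.

    Geometry per frame: one designated contact atom of set A sits at the
    origin and one of set B at (d_t, 0, 0), where d_t is drawn from
    N(target_mean, target_sd) (truncated at 0.1 Å).  All other atoms of each
    set are placed strictly farther from the opposing set, so the cross-set
    minimum equals d_t exactly.  With ``modes=2`` the draws alternate between
    two components at target_mean ± mode_separation/2 (equal weights),
    giving a bimodal series for conformer-split testing.  Frames are spaced
    ``frame_dt`` ps apart (the recording interval of a typical production
    run).  Atoms are carbons, so no element filtering interferes.
    """
    if n_frames < 1 or n_atoms_a < 1 or n_atoms_b < 1:
        raise ValidationError("counts must be >= 1")
    if not target_mean > target_sd or target_sd < 0:
        raise ValidationError("need target_mean > target_sd >= 0")
    if modes not in (1, 2):
        raise ValidationError("modes must be 1 or 2")
    if modes == 2 and target_mean - mode_separation / 2 <= target_sd:
        raise ValidationError("bimodal centers would imply non-positive distances")
    rng = np.random.default_rng(seed)
    if modes == 1:
        centers = np.full(n_frames, target_mean)
        labels = np.zeros(n_frames, dtype=int)
    else:
        labels = rng.integers(0, 2, n_frames)
        centers = target_mean + (labels - 0.5) * mode_separation
    d = rng.normal(centers, target_sd) if target_sd > 0 else centers.astype(float)
    d = np.maximum(d, 0.1)

    n_atoms = n_atoms_a + n_atoms_b
    coords = np.empty((n_frames, n_atoms, 3))
    for k in range(n_frames):
        # contact atoms define the minimum exactly; spectators sit farther out
        coords[k, 0] = (0.0, 0.0, 0.0)
        if n_atoms_a > 1:
            extra = rng.uniform(-1.0, 1.0, (n_atoms_a - 1, 3))
            extra[:, 0] = -rng.uniform(2.0, 5.0, n_atoms_a - 1)   # x <= -2
            coords[k, 1:n_atoms_a] = extra
        coords[k, n_atoms_a] = (d[k], 0.0, 0.0)
        if n_atoms_b > 1:
            extra = rng.uniform(-1.0, 1.0, (n_atoms_b - 1, 3))
            extra[:, 0] = d[k] + rng.uniform(2.0, 5.0, n_atoms_b - 1)  # x >= d+2
            coords[k, n_atoms_a + 1:] = extra
    names = tuple(f"C{i + 1}" for i in range(n_atoms))
    elements = ("C",) * n_atoms
    times = np.arange(n_frames, dtype=float) * frame_dt
    traj = Trajectory(coords, names, elements, times)
    truth = {
        "target_mean": target_mean,
        "target_sd": target_sd,
        "modes": modes,
        "mode_separation": mode_separation if modes == 2 else 0.0,
        "per_frame_min": d,
        "mode_labels": labels,
        "occupancy_low": float(np.mean(labels == 0)) if modes == 2 else 1.0,
        "selection_a": tuple(range(n_atoms_a)),
        "selection_b": tuple(range(n_atoms_a, n_atoms)),
        "seed": seed,
    }
    return traj, truth
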
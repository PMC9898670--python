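"""Bent-conformer ensembles of triple helices.

A force-field trajectory is not needed to pose the conformational-selection
question -- any pool of stereochemically acceptable conformers spanning the
bend range serves as the search space that scattering data then filter.  The
sampler here bends a linear model at a chosen hinge triplet: the C-terminal
arm is rotated rigidly about a random axis perpendicular to the helix axis
by an angle drawn from a prior (uniform on [0, max_bend] by default), the
bend being distributed over the hinge triplet by a one-triplet smoothing
ramp so the backbone is not broken.  Optional worm-like noise adds small
independent per-triplet rotations, giving the gentle conformational
dispersion seen in flexible helices.  Conformers that produce steric
clashes are resampled.  Everything is driven by one seeded generator, so
ensembles are bit-reproducible.

The bend angle of a conformer is measured exactly as it is defined for the
models: the angle between the principal axes of the two arms flanking the
hinge, zero for a straight helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helix_builder import TripleHelix, principal_axis, MIN_NONBONDED_DIST

__all__ = [
    "SamplerParams", "ConformerEnsemble", "BendMeasurement",
    "generate_conformers", "bend_angle", "default_hinge",
]


@dataclass(frozen=True)
class SamplerParams:
    """Hinge-bend sampler settings.

    hinge_triplet : 1-based triplet index carrying the hinge (must be
        strictly inside the helix, with >= 2 triplets on each side).
    max_bend : upper end of the uniform bend-angle prior, degrees.
    wormlike_sd : s.d. of the per-triplet worm-like angular noise,
        degrees per triplet (0 switches the noise off).
    """

    hinge_triplet: int
    max_bend: float = 90.0
    wormlike_sd: float = 0.0


@dataclass(frozen=True)
class BendMeasurement:
    angle: float                       # degrees, >= 0 (0 = straight)
    arm1_range: tuple[int, int]        # residue ranges used
    arm2_range: tuple[int, int]

    def __post_init__(self):
        if self.angle < 0:
            raise ValueError("bend angle must be >= 0")


@dataclass
class ConformerEnsemble:
    conformers: list[TripleHelix]
    params: SamplerParams
    seed: int
    bends_applied: np.ndarray          # degrees drawn from the prior
    n_resampled: int = 0

    @property
    def size(self) -> int:
        return len(self.conformers)


def default_hinge(chain_residues, n_triplets: int) -> int:
    """Default hinge: the interruption triplet when a Gln is present in the
    central region (the GQG-type break), otherwise the centre triplet."""
    seq = list(chain_residues)
    for i, code in enumerate(seq):
        if code == "Q":
            return min(max(i // 3 + 1, 3), n_triplets - 2)
    return max(n_triplets // 2, 3)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _apply_hinge(model: TripleHelix, hinge: int, angle_deg: float,
                 azimuth_axis: np.ndarray, helix_axis: np.ndarray) -> TripleHelix:
    """Rotate the C-terminal arm by angle_deg about the hinge point.

    Residues of the hinge triplet itself follow a linear ramp (1-triplet
    smoothing window); both arms move as rigid bodies.
    """
    out = model.copy()
    res_lo = 3 * (hinge - 1) + 1
    res_hi = 3 * hinge
    hinge_mask = (model.res_ids >= res_lo) & (model.res_ids <= res_hi)
    pivot = model.coords[hinge_mask & (model.atom_names == "CA")].mean(axis=0)
    # per-atom rotation fraction: 0 on the N arm, 1 on the C arm, ramped
    # across the hinge triplet
    frac = np.clip((model.res_ids - (res_lo - 0.5)) / (res_hi - res_lo + 1), 0.0, 1.0)
    angle = np.deg2rad(angle_deg)
    for f in np.unique(frac):
        if f == 0.0:
            continue
        rot = _rotation_matrix(azimuth_axis, f * angle)
        sel = frac == f
        out.coords[sel] = (out.coords[sel] - pivot) @ rot.T + pivot
    return out


def _apply_wormlike(model: TripleHelix, sd_deg: float,
                    rng: np.random.Generator) -> TripleHelix:
    """Small independent per-triplet rotations, accumulated down the chain."""
    out = model.copy()
    n_trip = model.n_triplets
    axis_main = principal_axis(model)
    for t in range(1, n_trip):
        ang = np.deg2rad(rng.normal(0.0, sd_deg))
        az = rng.uniform(0.0, 2.0 * np.pi)
        perp = _perpendicular_axis(axis_main, az)
        boundary = 3 * t
        sel = out.res_ids > boundary
        pivot = out.coords[(out.res_ids >= boundary - 1) &
                           (out.res_ids <= boundary + 1) &
                           (out.atom_names == "CA")].mean(axis=0)
        rot = _rotation_matrix(perp, ang)
        out.coords[sel] = (out.coords[sel] - pivot) @ rot.T + pivot
    return out


def _perpendicular_axis(axis: np.ndarray, azimuth: float) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.cos(azimuth) * e1 + np.sin(azimuth) * e2


def generate_conformers(base: TripleHelix, n: int, params: SamplerParams,
                        seed: int, max_resample: int = 50) -> ConformerEnsemble:
    """Generate a seeded ensemble of hinge-bent conformers.

    Each conformer applies (i) a rigid hinge bend of angle ~ U[0, max_bend]
    about a random perpendicular axis and (ii) optional worm-like noise.
    Conformers with steric clashes are redrawn (bounded retries).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    n_trip = base.n_triplets
    h = params.hinge_triplet
    if not (3 <= h <= n_trip - 2):
        raise ValueError(
            f"hinge triplet {h} must lie strictly inside the helix with two "
            f"triplets on each side (helix has {n_trip} triplets)")
    rng = np.random.default_rng(seed)
    helix_axis = principal_axis(base)
    conformers: list[TripleHelix] = []
    bends = np.empty(n)
    n_resampled = 0
    for j in range(n):
        for attempt in range(max_resample):
            angle = rng.uniform(0.0, params.max_bend) if params.max_bend > 0 else 0.0
            az = rng.uniform(0.0, 2.0 * np.pi)
            axis = _perpendicular_axis(helix_axis, az)
            conf = _apply_hinge(base, h, angle, axis, helix_axis)
            if params.wormlike_sd > 0:
                conf = _apply_wormlike(conf, params.wormlike_sd, rng)
            if conf.min_nonbonded_distance() >= MIN_NONBONDED_DIST:
                break
            n_resampled += 1
        else:
            raise RuntimeError(
                f"conformer {j}: {max_resample} consecutive steric-clash "
                "resamples; hinge/bend settings are producing collapsed models")
        conf.provenance = f"conformer(seed={seed},index={j})"
        conformers.append(conf)
        bends[j] = angle
    return ConformerEnsemble(conformers, params, seed, bends, n_resampled)


def _arm_axis(model: TripleHelix, res_range: tuple[int, int]) -> np.ndarray:
    """Principal axis of an arm from its triplet centroids.

    Each triplet's backbone centroid lies essentially on the local helix
    axis (the nine residues of a triplet sample most of a turn), so the
    dominant eigenvector of the centroid cloud tracks the arm direction
    without the azimuthal wobble a raw atom cloud has on short arms.
    """
    lo, hi = res_range
    chains = model.chains
    cents = []
    for start in range(lo + 2, hi - 1, 3):
        # stagger-aligned rung: chain k looks one residue earlier than the
        # previous chain, so the nine azimuths cancel by the 120-deg symmetry
        rung = []
        for k, cid in enumerate(chains):
            m = model.mask(chain=cid, res_range=(start - k, start - k + 2),
                           atoms=("CA",))
            if m.any():
                rung.append(model.coords[m].mean(axis=0))
        if len(rung) == len(chains):
            cents.append(np.mean(rung, axis=0))
    cents = np.array(cents)
    if len(cents) < 2:
        raise ValueError(f"arm {res_range} has fewer than two triplets")
    c = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, cents[-1] - cents[0]) < 0:
        axis = -axis
    return axis


def bend_angle(model: TripleHelix, hinge: int) -> BendMeasurement:
    """Bend at a hinge triplet: angle between the arms' principal axes.

    Both arms must span at least two triplets.  0 means collinear arms.
    """
    n_trip = model.n_triplets
    if not (3 <= hinge <= n_trip - 2):
        raise ValueError(f"hinge triplet {hinge} leaves an arm shorter than "
                         "two triplets")
    arm1 = (1, 3 * (hinge - 1))
    arm2 = (3 * hinge + 1, 3 * n_trip)
    a1 = _arm_axis(model, arm1)
    a2 = _arm_axis(model, arm2)
    cosang = float(np.clip(np.dot(a1, a2), -1.0, 1.0))
    return BendMeasurement(float(np.degrees(np.arccos(cosang))), arm1, arm2)
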
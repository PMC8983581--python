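"""Ground-truthed synthetic data for every pipeline stage.

The scene generator emulates two-channel confocal acquisition of a cell:
an ellipsoidal nucleus whose DNA channel carries a smoothed random texture,
containing non-overlapping spherical puncta whose core intensity is
``kp_true`` times the nucleoplasmic (light-phase) level.  Puncta are
painted with sub-voxel accuracy (supersampled partial-volume coverage),
blurred by an anisotropic Gaussian PSF, and degraded by Poisson photon
noise plus additive Gaussian read noise.  Every generated object is
recorded in a :class:`GroundTruth` so each downstream stage can be tested
by parameter recovery.

FRAP traces, dilution-series fields and FG-motif construct sequences are
generated from the same models the analysis modules fit, with all
randomness driven by explicit seeds: identical parameters and seed give
bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi

from .errors import ParameterError, PlacementError
from .frap import FrapTrace
from .invitro import DilutionSeries
from .io import ImageStack
from .seqfeatures import ProteinSequence

logger = logging.getLogger(__name__)

__all__ = [
    "SceneParams", "GroundTruth", "generate_cell_stack", "generate_frap_trace",
    "generate_dilution_series", "generate_construct_sequence",
    "frap_recovered_fraction", "plane_count", "axial_span",
]

#: residues free of F and G, so spacers can never create FG/GLFG motifs
_SPACER_ALPHABET = "ASTNQPVHKRDE"


def plane_count(span_um: float, interval_um: float) -> int:
    """Number of z-planes covering ``span_um`` at ``interval_um``, endpoints included."""
    if interval_um <= 0:
        raise ParameterError("plane interval must be positive")
    return int(round(span_um / interval_um)) + 1


def axial_span(n_planes: int, interval_um: float) -> float:
    """Axial distance covered by ``n_planes`` planes at ``interval_um`` spacing."""
    if n_planes < 1:
        raise ParameterError("need at least one plane")
    return (n_planes - 1) * interval_um


@dataclass
class SceneParams:
    """Parameters of one synthetic two-channel cell stack.

    All lengths in μm, intensities in arbitrary units.  ``kp_true`` is the
    dense/light intensity ratio of the puncta (≥ 1); ``dna_overlap`` is the
    fraction of puncta biased onto DNA-dense texture.  ``poisson_scale`` is
    the photon count per intensity unit (0 disables shot noise);
    ``gaussian_sd`` is additive read noise.
    """

    nucleus_semi_axes: tuple[float, float, float] = (2.2, 3.6, 3.6)  # (z, y, x)
    puncta_count: int = 80
    punctum_radius_mean: float = 0.30
    punctum_radius_sd: float = 0.04
    lp_intensity: float = 100.0
    kp_true: float = 10.0
    cytoplasm_intensity: float = 20.0
    dna_overlap: float = 0.5
    psf_sigma: tuple[float, float, float] = (0.25, 0.10, 0.10)  # (z, y, x)
    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)    # (z, y, x)
    seed: int = 0
    dna_mean: float = 80.0
    dna_contrast: float = 0.5
    dna_texture_sigma: float = 0.4
    dna_background: float = 2.0
    margin_um: float = 0.8
    cytoplasm_puncta_count: int = 0
    min_separation_um: float = 0.1     # gap between punctum surfaces
    shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if any(a <= 0 for a in self.nucleus_semi_axes):
            raise ParameterError("nucleus semi-axes must be positive")
        if self.puncta_count < 0 or self.cytoplasm_puncta_count < 0:
            raise ParameterError("puncta counts must be >= 0")
        if self.punctum_radius_mean <= 0 or self.punctum_radius_sd < 0:
            raise ParameterError("punctum radius must be positive")
        if self.kp_true < 1:
            raise ParameterError("kp_true must be >= 1")
        if self.lp_intensity <= 0:
            raise ParameterError("lp_intensity must be positive")
        if not 0 <= self.dna_overlap <= 1:
            raise ParameterError("dna_overlap must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneParams":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("nucleus_semi_axes", "psf_sigma", "voxel_size", "shape"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """True scene parameters recorded at generation time."""

    centers_um: list[tuple[float, float, float]] = field(default_factory=list)
    radii_um: list[float] = field(default_factory=list)
    volumes_um3: list[float] = field(default_factory=list)    # (4/3)πr³
    in_nucleus: list[bool] = field(default_factory=list)
    nucleus_volume_um3: float = 0.0
    nucleus_center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kp_true: float = 1.0
    lp_intensity: float = 0.0
    t_half: float | None = None
    m_f: float | None = None
    csat_true: float | None = None

    @property
    def n_objects(self) -> int:
        return len(self.centers_um)

    def records(self) -> list[dict]:
        """Per-punctum rows for a truth CSV."""
        return [
            {"punctum": i + 1, "z_um": c[0], "y_um": c[1], "x_um": c[2],
             "radius_um": r, "volume_um3": v, "in_nucleus": n}
            for i, (c, r, v, n) in enumerate(
                zip(self.centers_um, self.radii_um, self.volumes_um3, self.in_nucleus))
        ]


def _supersampled_ball(center_um, radius_um, voxel_size, shape, factor=3):
    """Partial-volume coverage of a sphere on the voxel grid (bbox slices, weights)."""
    vs = np.asarray(voxel_size)
    lo = np.maximum(np.floor((np.asarray(center_um) - radius_um) / vs - 1), 0).astype(int)
    hi = np.minimum(np.ceil((np.asarray(center_um) + radius_um) / vs + 1),
                    np.asarray(shape)).astype(int)
    if np.any(lo >= hi):
        return None, None
    axes = []
    for a in range(3):
        idx = np.arange(lo[a], hi[a])
        sub = (np.arange(factor) + 0.5) / factor - 0.5
        axes.append(((idx[:, None] + sub[None, :]) * vs[a] - center_um[a]).reshape(-1))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    fine = (zz ** 2 + yy ** 2 + xx ** 2) <= radius_um ** 2
    n = hi - lo
    cov = fine.reshape(n[0], factor, n[1], factor, n[2], factor).mean(axis=(1, 3, 5))
    return tuple(slice(l, h) for l, h in zip(lo, hi)), cov


def _ellipsoid_coverage(center_um, semi_axes, voxel_size, shape, edge_um=0.08):
    """Soft-edged ellipsoid indicator (approximate signed distance ramp)."""
    coords = [ (np.arange(n) * v - c)
               for n, v, c in zip(shape, voxel_size, center_um) ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    a, b, c = semi_axes
    e2 = (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2
    e = np.sqrt(e2)
    grad = np.sqrt((zz / a ** 2) ** 2 + (yy / b ** 2) ** 2 + (xx / c ** 2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        signed = np.where(grad > 0, (1.0 - e) * e / grad, 1.0)  # >0 inside
    return np.clip(signed / (2 * edge_um) + 0.5, 0.0, 1.0), e


def _place_puncta(rng, params: SceneParams, texture, ell_norm, center_um, shape):
    """Sample non-overlapping punctum centers/radii; raises PlacementError."""
    vs = np.asarray(params.voxel_size)
    semi = np.asarray(params.nucleus_semi_axes)
    centers, radii, in_nuc = [], [], []
    nuc_vals = texture[ell_norm < 0.95]
    textured = nuc_vals.size > 0 and np.ptp(nuc_vals) > 1e-9
    hi_thr = np.quantile(nuc_vals, 0.6) if textured else 0.0
    lo_thr = np.quantile(nuc_vals, 0.4) if textured else 0.0

    budget = 2000 * max(params.puncta_count + params.cytoplasm_puncta_count, 1)
    tries = 0

    def _ok_distance(pos, r):
        for c, rr in zip(centers, radii):
            if np.linalg.norm(np.asarray(c) - pos) < r + rr + params.min_separation_um:
                return False
        return True

    for i in range(params.puncta_count):
        want_hi = rng.random() < params.dna_overlap
        while True:
            tries += 1
            if tries > budget:
                raise PlacementError(
                    f"placed {len(centers)}/{params.puncta_count} puncta within "
                    f"the retry budget; reduce count or radius")
            r = max(float(rng.normal(params.punctum_radius_mean,
                                     params.punctum_radius_sd)),
                    0.4 * params.punctum_radius_mean)
            # uniform in the ellipsoid shrunk by r + margin on every axis
            shrink = semi - (r + 0.05)
            if np.any(shrink <= 0):
                continue
            u = rng.uniform(-1, 1, 3)
            if np.sum(u ** 2) > 1:
                continue
            pos = np.asarray(center_um) + u * shrink
            vox = tuple(np.clip(np.round(pos / vs).astype(int), 0,
                                np.asarray(shape) - 1))
            tex = texture[vox]
            if textured:
                if want_hi and tex < hi_thr:
                    continue
                if not want_hi and tex > lo_thr:
                    continue
            if _ok_distance(pos, r):
                centers.append(tuple(pos)); radii.append(r); in_nuc.append(True)
                break

    extent = vs * (np.asarray(shape) - 1)
    for i in range(params.cytoplasm_puncta_count):
        while True:
            tries += 1
            if tries > budget:
                raise PlacementError("could not place cytoplasmic puncta in budget")
            r = max(float(rng.normal(params.punctum_radius_mean,
                                     params.punctum_radius_sd)),
                    0.4 * params.punctum_radius_mean)
            pos = rng.uniform(r + 0.05, extent - (r + 0.05))
            norm = np.sqrt(np.sum(((pos - center_um) / (semi + r + 0.1)) ** 2))
            if norm <= 1.0:       # would intrude into the nucleus
                continue
            if _ok_distance(pos, r):
                centers.append(tuple(pos)); radii.append(r); in_nuc.append(False)
                break
    return centers, radii, in_nuc


def generate_cell_stack(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Render one two-channel (protein, DNA) stack plus its ground truth.

    With noise disabled the mean non-punctum in-nucleus intensity equals
    ``lp_intensity`` and punctum cores are ``kp_true × lp_intensity``
    before PSF blur; total intensity matches the analytic scene integral to
    within sub-voxel discretization error.
    """
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size)
    semi = np.asarray(params.nucleus_semi_axes)
    if params.shape is not None:
        shape = tuple(params.shape)
    else:
        shape = tuple(int(np.ceil(2 * (s + params.margin_um) / v)) + 1
                      for s, v in zip(semi, vs))
    center_um = tuple((np.asarray(shape) - 1) / 2 * vs)

    nuc_cov, ell_norm = _ellipsoid_coverage(center_um, semi, vs, shape)

    # DNA texture: smoothed white noise, rescaled to the requested contrast
    tex = rng.standard_normal(shape)
    tex = ndi.gaussian_filter(tex, params.dna_texture_sigma / vs)
    sd = tex.std()
    if sd > 0:
        tex = tex / sd
    dna_in = params.dna_mean * (1.0 + params.dna_contrast * tex)
    dna_in = np.clip(dna_in, 0.05 * params.dna_mean, None)
    dna = params.dna_background + (dna_in - params.dna_background) * nuc_cov

    centers, radii, in_nuc = _place_puncta(rng, params, dna_in, ell_norm,
                                           center_um, shape)

    protein = params.cytoplasm_intensity + \
        (params.lp_intensity - params.cytoplasm_intensity) * nuc_cov
    excess = (params.kp_true - 1.0) * params.lp_intensity
    for c, r, inside in zip(centers, radii, in_nuc):
        sl, cov = _supersampled_ball(c, r, vs, shape)
        if sl is None:
            continue
        protein[sl] += excess * cov
        # boost DNA texture under overlap-placed puncta is already implicit
        # in the placement bias; the DNA channel itself is left untouched.

    if any(s > 1e-6 for s in params.psf_sigma):
        sig = np.asarray(params.psf_sigma) / vs
        protein = ndi.gaussian_filter(protein, sig, mode="nearest")
        dna = ndi.gaussian_filter(dna, sig, mode="nearest")

    if params.poisson_scale > 0:
        protein = rng.poisson(np.clip(protein, 0, None) * params.poisson_scale
                              ).astype(float) / params.poisson_scale
        dna = rng.poisson(np.clip(dna, 0, None) * params.poisson_scale
                          ).astype(float) / params.poisson_scale
    if params.gaussian_sd > 0:
        protein = protein + rng.normal(0, params.gaussian_sd, shape)
        dna = dna + rng.normal(0, params.gaussian_sd, shape)
    protein = np.clip(protein, 0, None)
    dna = np.clip(dna, 0, None)

    stack = ImageStack(np.stack([protein, dna]), tuple(vs),
                       channel_names=("protein", "dna"))
    truth = GroundTruth(
        centers_um=centers, radii_um=radii,
        volumes_um3=[4.0 / 3.0 * math.pi * r ** 3 for r in radii],
        in_nucleus=in_nuc,
        nucleus_volume_um3=4.0 / 3.0 * math.pi * float(np.prod(semi)),
        nucleus_center_um=center_um,
        kp_true=params.kp_true, lp_intensity=params.lp_intensity,
    )
    return stack, truth


def frap_recovered_fraction(t, t_half: float, m_f: float):
    """Noiseless recovered fraction m_f·(1 − 2^(−t/t_half))."""
    if t_half <= 0:
        raise ParameterError("t_half must be positive")
    return m_f * (1.0 - 2.0 ** (-np.asarray(t, float) / t_half))


def generate_frap_trace(
    t_half: float,
    m_f: float,
    noise_sd: float = 0.0,
    n_points: int = 60,
    seed: int = 0,
    bleach_depth: float = 0.5,
    t_max: float | None = None,
    background: float = 50.0,
    scale: float = 1000.0,
    reference_decay: float = 0.0,
) -> FrapTrace:
    """Raw FRAP trace from the single-exponential recovery model.

    ``bleach_depth`` is the post-bleach fraction of the pre-bleach signal
    (0.5 = bleached to 50%); ``noise_sd`` is Gaussian noise as a fraction of
    the pre-bleach signal; ``reference_decay`` (1/s) applies exponential
    acquisition photobleaching to both ROI and reference, which the
    reference normalization must cancel.
    """
    if t_half <= 0:
        raise ParameterError("t_half must be positive")
    if not 0 < m_f <= 1:
        raise ParameterError("m_f must lie in (0, 1]")
    if not 0 <= bleach_depth < 1:
        raise ParameterError("bleach_depth must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t_max = 6.0 * t_half if t_max is None else t_max
    time = np.linspace(0.0, t_max, n_points)
    drift = np.exp(-reference_decay * time)
    normalized = bleach_depth + (1.0 - bleach_depth) * \
        frap_recovered_fraction(time, t_half, m_f)
    roi = background + scale * normalized * drift
    reference = background + scale * drift
    if noise_sd > 0:
        roi = roi + rng.normal(0, noise_sd * scale, n_points)
        reference = reference + rng.normal(0, noise_sd * scale / 4, n_points)
    return FrapTrace(time=time, roi=roi, background=np.full(n_points, background),
                     reference=reference, prebleach=background + scale)


def generate_dilution_series(
    csat_true: float,
    concentrations: Sequence[float],
    seed: int = 0,
    pixel_size: float = 0.1,
    field_px: int = 192,
    spot_sigma_um: float = 0.25,
    background: float = 10.0,
    amplitude: float = 200.0,
    noise_sd: float = 1.0,
) -> DilutionSeries:
    """Dilution-series fields: condensate-free below ``csat_true``, and a
    condensate count growing with concentration at or above it."""
    concs = [float(c) for c in concentrations]
    if len(concs) == 0:
        raise ParameterError("empty concentration list")
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ParameterError("concentrations must be sorted ascending")
    if csat_true <= 0:
        raise ParameterError("csat_true must be positive")
    rng = np.random.default_rng(seed)
    sigma_px = spot_sigma_um / pixel_size
    margin = int(np.ceil(4 * sigma_px)) + 1
    images, true_counts = [], []
    for conc in concs:
        img = np.full((field_px, field_px), background, float)
        if conc >= csat_true:
            n = 3 + int(np.floor(6.0 * np.log2(conc / csat_true)))
        else:
            n = 0
        placed = []
        attempts = 0
        while len(placed) < n and attempts < 20000:
            attempts += 1
            pos = rng.uniform(margin, field_px - margin, 2)
            if all(np.hypot(*(pos - q)) > 8 * sigma_px for q in placed):
                placed.append(pos)
        if len(placed) < n:
            raise PlacementError(f"could not place {n} condensates in the field")
        yy, xx = np.mgrid[0:field_px, 0:field_px]
        for pos in placed:
            d2 = (yy - pos[0]) ** 2 + (xx - pos[1]) ** 2
            img += amplitude * np.exp(-d2 / (2 * sigma_px ** 2))
        if noise_sd > 0:
            img += rng.normal(0, noise_sd, img.shape)
        images.append(np.clip(img, 0, None))
        true_counts.append(n)
    return DilutionSeries(concentrations=concs, images=images,
                          pixel_size=pixel_size, true_counts=true_counts)


def _spacer(rng, lo=3, hi=7) -> str:
    n = int(rng.integers(lo, hi))
    return "".join(rng.choice(list(_SPACER_ALPHABET), n))


def _fg_region(rng, n_fg: int, n_glfg: int) -> str:
    motifs = ["GLFG"] * n_glfg + ["FG"] * (n_fg - n_glfg)
    rng.shuffle(motifs)
    parts = [_spacer(rng)]
    for m in motifs:
        parts.append(m)
        parts.append(_spacer(rng))
    return "".join(parts)


def generate_construct_sequence(
    n_fg_nterm: int,
    n_fg_cterm: int,
    n_glfg_nterm: int = 0,
    n_glfg_cterm: int = 0,
    seed: int = 0,
) -> ProteinSequence:
    """Synthetic two-region FG-repeat construct with exact motif counts.

    The emitted sequence contains exactly ``n_fg_nterm`` FG motifs (of which
    ``n_glfg_nterm`` sit in GLFG context) in the annotated ``nterm_fg``
    region and likewise for the C-terminal region; spacer residues exclude
    F and G so no accidental motifs can arise.
    """
    for n in (n_fg_nterm, n_fg_cterm, n_glfg_nterm, n_glfg_cterm):
        if n < 0:
            raise ParameterError("motif counts must be non-negative")
    if n_glfg_nterm > n_fg_nterm or n_glfg_cterm > n_fg_cterm:
        raise ParameterError("GLFG count cannot exceed FG count in a region")
    rng = np.random.default_rng(seed)
    nterm = _fg_region(rng, n_fg_nterm, n_glfg_nterm)
    linker = _spacer(rng, 8, 13)
    cterm = _fg_region(rng, n_fg_cterm, n_glfg_cterm)
    residues = nterm + linker + cterm
    regions = {
        "nterm_fg": (1, len(nterm)),
        "cterm_fg": (len(nterm) + len(linker) + 1, len(residues)),
    }
    return ProteinSequence(
        id=f"synthetic_fg_construct_n{n_fg_nterm}_c{n_fg_cterm}",
        residues=residues, regions=regions,
    )
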
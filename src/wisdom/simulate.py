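"""Synthetic patient-bag simulator.

Generates cohorts of "patients", each a bag of MRI-visible lymph-node
patches, with the population structure weak supervision assumes: only
patient-level pathology (binary metastasis status, resected and metastatic
node counts) is observed during training, while the per-node metastatic
truth is kept as a latent field for evaluation only.

Cohort-level defaults follow the clinical statistics of a large rectal
cancer surgery series: about 14 +/- 5 visible nodes per patient (range
5-50), 39% of patients node-positive, and a heavily overdispersed
metastatic-node count (mean 1.6, SD 3.2, range 0-35 across all patients),
modelled as a zero-truncated negative binomial among positive patients.
Metastatic nodes are drawn with larger diameters (multiplicative
``size_effect``), shifted mean ADC (additive ``adc_effect``, positive by
default) and an intranodal or perinodal high-contrast texture blob whose
amplitude is ``texture_effect``; setting an effect to its neutral value
removes that channel of signal entirely, which is how null cohorts for
negative-control experiments are built.

Per-node features recorded in the bag (diameters, ratio, mean ADC) are
*measured back* from the rendered mask and ADC patch with
:mod:`wisdom.features`, so the simulator and the feature pipeline are
consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, GenerationError
from .features import SpacingInfo, compute_diameters, mean_adc
from .staging import Stage, count_to_stage

__all__ = [
    "CohortParams",
    "LymphNodeInstance",
    "PatientBag",
    "render_patch",
    "generate_cohort",
]

_BENIGN_LONG_MEDIAN_MM = 6.5   # log-normal median long axis of benign nodes
_BENIGN_LONG_SIGMA = 0.30      # log-scale SD
_BENIGN_ADC_MEAN = 1.10        # 10^-3 mm^2/s
_ADC_SD = 0.12
_BACKGROUND_NOISE_SD = 0.30    # T2-like patch background noise
_NODE_CONTRAST = 1.0           # mean in-node intensity above background
_BLOB_SIGMA_MM = 1.2           # texture blob width


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_patients : int
        Number of patient bags to generate.
    patient_lnm_rate : float
        Probability that a patient has >= 1 metastatic resected node.
    visible_ln_mean, visible_ln_sd : float
        Mean / SD of the per-patient visible-node count, truncated to
        [5, 50] before rounding.
    met_count_mean : float
        Mean of the (untruncated) negative-binomial metastatic count among
        node-positive patients. The default 4.1 makes the all-patient
        mixture mean ~1.6 at the default 39% positivity rate.
    met_count_dispersion : float
        Negative-binomial size parameter r (variance = mu + mu^2 / r);
        small r gives the heavy tail needed for SD ~3.2 at mean 1.6.
    size_effect : float
        Multiplier on metastatic-node diameters (1 = no size signal).
    adc_effect : float
        Additive shift of metastatic-node mean ADC in 10^-3 mm^2/s
        (0 = no diffusion signal). Positive by default.
    texture_effect : float
        Amplitude of the intranodal/perinodal high-contrast blob rendered
        into metastatic patches (0 = metastatic and benign patches are
        drawn from the same image distribution).
    hidden_node_rate : float
        Fraction of resected nodes invisible at MRI. Hidden nodes enter
        the pathology counts (the proportion denominator) but not the bag,
        reproducing the mismatch between MRI-visible and resected nodes.
    patch_px : int
        Patch side length in pixels (>= 16).
    pixel_spacing : float
        In-plane spacing, mm/pixel.
    render_patches : bool
        When False, skip image rendering and only draw features; masks,
        patches and ADC maps are then absent. Used for fast cohort-level
        statistical checks.
    seed : int
        Global seed; each patient gets an independent child stream, so
        cohorts are reproducible and order-independent.
    """

    n_patients: int = 200
    patient_lnm_rate: float = 0.39
    visible_ln_mean: float = 14.0
    visible_ln_sd: float = 5.0
    met_count_mean: float = 4.1
    met_count_dispersion: float = 1.4
    size_effect: float = 1.5
    adc_effect: float = 0.25
    texture_effect: float = 1.0
    hidden_node_rate: float = 0.0
    patch_px: int = 32
    pixel_spacing: float = 0.5
    render_patches: bool = True
    seed: int = 0

    def __post_init__(self):
        def fail(name, msg):
            raise ConfigurationError(f"CohortParams.{name}: {msg}")

        if self.n_patients < 1:
            fail("n_patients", f"must be >= 1, got {self.n_patients}")
        for name in ("patient_lnm_rate", "hidden_node_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                fail(name, f"must be in [0, 1], got {v}")
        if not 5.0 <= self.visible_ln_mean <= 50.0:
            fail("visible_ln_mean", f"must be in [5, 50], got {self.visible_ln_mean}")
        if self.visible_ln_sd < 0:
            fail("visible_ln_sd", f"must be >= 0, got {self.visible_ln_sd}")
        if self.met_count_mean <= 0:
            fail("met_count_mean", f"must be > 0, got {self.met_count_mean}")
        if self.met_count_dispersion <= 0:
            fail("met_count_dispersion", f"must be > 0, got {self.met_count_dispersion}")
        if self.size_effect <= 0:
            fail("size_effect", f"must be > 0, got {self.size_effect}")
        if self.texture_effect < 0:
            fail("texture_effect", f"must be >= 0, got {self.texture_effect}")
        if self.patch_px < 16:
            fail("patch_px", f"must be >= 16, got {self.patch_px}")
        if self.pixel_spacing <= 0:
            fail("pixel_spacing", f"must be > 0, got {self.pixel_spacing}")

    @classmethod
    def null_signal(cls, **kw) -> "CohortParams":
        """A cohort with no node-level signal in any channel.

        Latent labels still exist at the bag level, but patches, sizes and
        ADC of metastatic and benign nodes are identically distributed —
        the negative control for label-recovery experiments.
        """
        kw.setdefault("texture_effect", 0.0)
        kw.setdefault("size_effect", 1.0)
        kw.setdefault("adc_effect", 0.0)
        return cls(**kw)

    @classmethod
    def strong_signal(cls, **kw) -> "CohortParams":
        """A cohort with clearly separable metastatic texture, size and ADC."""
        kw.setdefault("texture_effect", 3.0)
        kw.setdefault("size_effect", 1.6)
        kw.setdefault("adc_effect", 0.40)
        return cls(**kw)

    def replace(self, **kw) -> "CohortParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class LymphNodeInstance:
    """One MRI-visible lymph node (an instance within a patient bag)."""

    node_id: str
    long_diam_mm: float
    short_diam_mm: float
    diam_ratio: float
    mean_adc: Optional[float]
    latent_met: Optional[bool] = None
    prob: Optional[float] = None
    patch: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    adc_patch: Optional[np.ndarray] = None

    def __post_init__(self):
        if not 0 < self.short_diam_mm <= self.long_diam_mm:
            raise ConfigurationError(
                f"LymphNodeInstance {self.node_id}: need 0 < short <= long, got "
                f"({self.short_diam_mm}, {self.long_diam_mm})"
            )
        if not 0 < self.diam_ratio <= 1.0 + 1e-12:
            raise ConfigurationError(
                f"LymphNodeInstance {self.node_id}: diam_ratio must be in (0, 1], "
                f"got {self.diam_ratio}"
            )
        if self.mask is not None and not (np.asarray(self.mask) > 0.5).any():
            raise ConfigurationError(
                f"LymphNodeInstance {self.node_id}: mask is empty"
            )


@dataclass
class PatientBag:
    """A patient's MRI-visible nodes plus patient-level pathology labels."""

    patient_id: str
    nodes: list
    n_resected: int
    n_metastatic: int
    enroll_key: int = 0

    def __post_init__(self):
        if not 0 <= self.n_metastatic <= self.n_resected:
            raise ConfigurationError(
                f"PatientBag {self.patient_id}: need 0 <= n_metastatic <= "
                f"n_resected, got ({self.n_metastatic}, {self.n_resected})"
            )
        if len(self.nodes) == 0:
            raise ConfigurationError(f"PatientBag {self.patient_id}: empty bag")

    @property
    def y(self) -> int:
        """Binary patient label: 1 iff any resected node was metastatic."""
        return int(self.n_metastatic > 0)

    @property
    def rho(self) -> float:
        """Metastatic proportion among resected nodes (the LLP target)."""
        return self.n_metastatic / self.n_resected

    @property
    def stage_true(self) -> Stage:
        return count_to_stage(self.n_metastatic)

    def __len__(self) -> int:
        return len(self.nodes)


def _gaussian_blob(shape, center, sigma_px):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma_px**2))


def render_patch(
    latent_met: bool,
    diam_mm: tuple,
    texture_effect: float,
    spacing: float,
    rng: np.random.Generator,
    patch_px: int = 32,
    adc_target: Optional[float] = None,
):
    """Render one node patch: (T2-like patch, binary mask, ADC patch).

    The mask is a filled, randomly oriented ellipse with the requested long
    and short diameters (measured diameters round-trip within one pixel).
    The patch is Gaussian background noise plus a uniform in-node contrast;
    metastatic nodes additionally receive a high-contrast Gaussian blob
    placed intranodally or perinodally (coin flip) with amplitude
    ``texture_effect``. With ``texture_effect = 0`` metastatic and benign
    patches are statistically identical. The ADC patch is smooth tissue
    background with the node region set around ``adc_target``.
    """
    long_mm, short_mm = float(max(diam_mm)), float(min(diam_mm))
    r_long = long_mm / (2.0 * spacing)
    r_short = short_mm / (2.0 * spacing)
    if 2.0 * r_long + 2.0 > patch_px:
        raise GenerationError(
            f"render_patch: node long axis {long_mm} mm does not fit a "
            f"{patch_px} px patch at {spacing} mm/px"
        )
    center = (patch_px / 2.0 - 0.5, patch_px / 2.0 - 0.5)
    theta = rng.uniform(0.0, np.pi)
    mask = np.zeros((patch_px, patch_px), dtype=bool)
    rr, cc = draw_ellipse(
        center[0], center[1], r_long, r_short, shape=mask.shape, rotation=theta
    )
    mask[rr, cc] = True

    patch = rng.normal(0.0, _BACKGROUND_NOISE_SD, size=mask.shape)
    patch[mask] += _NODE_CONTRAST + rng.normal(0.0, 0.1)
    if latent_met and texture_effect > 0:
        sigma_px = max(_BLOB_SIGMA_MM / spacing, 1.0)
        u = rng.uniform(-0.6, 0.6, size=2)
        if rng.random() < 0.5:  # intranodal hotspot
            brow = center[0] + u[0] * r_short
            bcol = center[1] + u[1] * r_short
        else:  # perinodal hotspot, just beyond the boundary
            ang = rng.uniform(0.0, 2 * np.pi)
            rad = r_long + 1.0 + rng.uniform(0.0, 2.0)
            brow = np.clip(center[0] + rad * np.sin(ang), 1, patch_px - 2)
            bcol = np.clip(center[1] + rad * np.cos(ang), 1, patch_px - 2)
        patch += texture_effect * _gaussian_blob(mask.shape, (brow, bcol), sigma_px)

    if adc_target is None:
        adc_patch = None
    else:
        adc_patch = rng.normal(1.60, 0.10, size=mask.shape)
        adc_patch[mask] = adc_target + rng.normal(0.0, 0.03, size=int(mask.sum()))
        adc_patch = np.clip(adc_patch, 0.1, 3.5)
    return patch.astype(np.float32), mask, (
        None if adc_patch is None else adc_patch.astype(np.float32)
    )


def _draw_visible_count(rng, params) -> int:
    while True:
        v = rng.normal(params.visible_ln_mean, params.visible_ln_sd)
        if 5.0 <= v <= 50.0:
            return int(round(v))


def _draw_met_count(rng, params, n_resected) -> int:
    """Zero-truncated negative binomial, capped at min(35, n_resected)."""
    r = params.met_count_dispersion
    p = r / (r + params.met_count_mean)
    for _ in range(1000):
        k = rng.negative_binomial(r, p)
        if k >= 1:
            return int(min(k, 35, n_resected))
    return 1  # pragma: no cover - p(zero)^1000 is negligible


def _generate_patient(pid: int, seed_seq, params: CohortParams) -> PatientBag:
    rng = np.random.default_rng(seed_seq)
    n_visible = _draw_visible_count(rng, params)
    h = params.hidden_node_rate
    n_hidden = int(rng.poisson(n_visible * h / (1.0 - h))) if h > 0 else 0
    n_resected = n_visible + n_hidden

    positive = rng.random() < params.patient_lnm_rate
    n_met = _draw_met_count(rng, params, n_resected) if positive else 0
    # metastatic status assigned uniformly over resected nodes; the first
    # n_visible slots of the permutation are the MRI-visible ones
    flags = np.zeros(n_resected, dtype=bool)
    flags[:n_met] = True
    flags = rng.permutation(flags)
    visible_met = flags[:n_visible]

    max_long = (params.patch_px - 3) * params.pixel_spacing
    spacing = SpacingInfo.isotropic(params.pixel_spacing)
    nodes = []
    for j in range(n_visible):
        met = bool(visible_met[j])
        long_mm = rng.lognormal(np.log(_BENIGN_LONG_MEDIAN_MM), _BENIGN_LONG_SIGMA)
        if met:
            long_mm *= params.size_effect
        long_mm = float(np.clip(long_mm, 2.5, max_long))
        ratio = rng.uniform(0.45, 0.90)
        short_mm = max(long_mm * ratio, 2.0)
        adc = rng.normal(
            _BENIGN_ADC_MEAN + (params.adc_effect if met else 0.0), _ADC_SD
        )
        adc = float(np.clip(adc, 0.4, 3.0))
        node_id = f"P{pid:04d}_N{j:02d}"
        if params.render_patches:
            patch, mask, adc_patch = render_patch(
                met,
                (long_mm, short_mm),
                params.texture_effect,
                params.pixel_spacing,
                rng,
                patch_px=params.patch_px,
                adc_target=adc,
            )
            ld, sd, ratio_m = compute_diameters(mask, spacing)
            node = LymphNodeInstance(
                node_id=node_id,
                long_diam_mm=ld,
                short_diam_mm=sd,
                diam_ratio=ratio_m,
                mean_adc=mean_adc(mask, adc_patch),
                latent_met=met,
                patch=patch,
                mask=mask,
                adc_patch=adc_patch,
            )
        else:
            node = LymphNodeInstance(
                node_id=node_id,
                long_diam_mm=long_mm,
                short_diam_mm=short_mm,
                diam_ratio=short_mm / long_mm,
                mean_adc=adc,
                latent_met=met,
            )
        nodes.append(node)
    return PatientBag(
        patient_id=f"P{pid:04d}",
        nodes=nodes,
        n_resected=n_resected,
        n_metastatic=n_met,
        enroll_key=pid,
    )


def generate_cohort(params: CohortParams) -> list:
    """Generate ``params.n_patients`` internally consistent patient bags.

    Deterministic for a fixed seed; each patient is driven by an
    independent child of the global seed, so the cohort is invariant to
    generation order and any prefix of it is reproducible.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    return [_generate_patient(i, s, params) for i, s in enumerate(children)]
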
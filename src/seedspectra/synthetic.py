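"""Synthetic petri-dish scenes and seed-lot label tables.

This module emulates the acquisition conditions the analysis pipeline assumes: a
petri dish of 25 cowpea seeds imaged at 20 LED bands (375–970 nm), where
accelerated ageing depresses reflectance in the 505–780 nm range and raises it
above 780 nm, and every seed carries germination/vigor/seedling labels.

Nothing here touches real instrument data; the generator exists so that
segmentation, spectral extraction and the discriminant models can be exercised
and validated end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cube import DEFAULT_WAVELENGTHS_NM, MultispectralCube, WavelengthGrid
from .exceptions import ParameterError, PlacementError, ValidationError

__all__ = [
    "ClassSpectralProfile",
    "SceneSpec",
    "SeedTruth",
    "SceneTruth",
    "SeedLotLabels",
    "default_seed_profile",
    "default_background_profile",
    "default_dish_profile",
    "make_ageing_profiles",
    "render_scene",
    "make_labels",
    "AGEING_CLASSES",
]

#: Accelerated-ageing treatment labels, by incubation duration in hours.
AGEING_CLASSES: tuple[str, ...] = ("Non-aged", "AA24", "AA48", "AA72", "AA96")

_AGEING_HOURS: Mapping[str, int] = {
    "Non-aged": 0, "AA24": 24, "AA48": 48, "AA72": 72, "AA96": 96,
}

# Spectral windows of the ageing response: visible reflectance is depressed
# between 505 and 780 nm, NIR reflectance above 780 nm is elevated, and the
# 375–470 nm bands are left untouched (aged and non-aged seeds are nearly
# indistinguishable there).
_VIS_LO, _VIS_HI = 505.0, 780.0
_UV_HI = 470.0


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Mean reflectance signature of one seed class plus its variability.

    Parameters
    ----------
    class_name
        Label of the class this profile renders.
    mean_reflectance
        One mean reflectance per band, each in (0, 1.5).
    seed_level_sd
        Between-seed standard deviation: each rendered seed draws a per-band
        Gaussian offset with this SD around the class mean.
    pixel_noise_sd
        Within-seed pixel noise SD, applied independently per pixel and band.
    """

    class_name: str
    mean_reflectance: tuple[float, ...]
    seed_level_sd: float = 0.0
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        mr = tuple(float(v) for v in self.mean_reflectance)
        if any(not (0.0 < v < 1.5) for v in mr):
            raise ParameterError(
                f"profile '{self.class_name}': mean reflectance must lie in "
                f"(0, 1.5), got range [{min(mr):.3g}, {max(mr):.3g}]"
            )
        if self.seed_level_sd < 0 or self.pixel_noise_sd < 0:
            raise ParameterError("profile standard deviations must be >= 0")
        object.__setattr__(self, "mean_reflectance", mr)

    @property
    def n_bands(self) -> int:
        return len(self.mean_reflectance)


def default_seed_profile(
    grid: WavelengthGrid | None = None,
    seed_level_sd: float = 0.01,
    pixel_noise_sd: float = 0.02,
) -> ClassSpectralProfile:
    """Baseline (non-aged) cowpea seed reflectance signature.

    The shape mimics a cream-coloured legume seed coat: low UV reflectance
    rising through the visible to a broad NIR plateau, dipping slightly at the
    940/970 nm water/lipid bands.
    """
    grid = grid or WavelengthGrid()
    if tuple(grid.wavelengths_nm) != DEFAULT_WAVELENGTHS_NM:
        raise ParameterError("the default seed profile is defined on the 20-band grid")
    means = (
        0.08, 0.10, 0.13, 0.15, 0.18, 0.25, 0.30, 0.38, 0.42, 0.46,
        0.48, 0.50, 0.55, 0.60, 0.62, 0.63, 0.63, 0.64, 0.60, 0.55,
    )
    return ClassSpectralProfile("Non-aged", means, seed_level_sd, pixel_noise_sd)


def default_background_profile(n_bands: int = 20) -> ClassSpectralProfile:
    """Dark matte background surrounding the dish (near-black at all bands)."""
    return ClassSpectralProfile("background", (0.04,) * n_bands, 0.0, 0.005)


def default_dish_profile(n_bands: int = 20) -> ClassSpectralProfile:
    """Petri dish with wet filter paper: flat, clearly darker than seeds at 780 nm."""
    return ClassSpectralProfile("dish", (0.22,) * n_bands, 0.0, 0.01)


def make_ageing_profiles(
    base_profile: ClassSpectralProfile,
    vis_drop_per_24h: float = 0.02,
    nir_rise_per_24h: float = 0.01,
    grid: WavelengthGrid | None = None,
) -> dict[str, ClassSpectralProfile]:
    """Derive the five accelerated-ageing class profiles from a base signature.

    For an ageing duration of ``d`` hours the 505–780 nm bands are scaled by
    ``1 - (d/24) * vis_drop_per_24h`` and the bands above 780 nm by
    ``1 + (d/24) * nir_rise_per_24h``; bands at or below 470 nm are unchanged.
    This reproduces, by construction, the qualitative ageing response: aged
    seeds darker in the visible, brighter in the NIR.

    Parameters
    ----------
    base_profile
        The non-aged signature; variability parameters are inherited.
    vis_drop_per_24h, nir_rise_per_24h
        Fractional reflectance change per 24 h of ageing; must be >= 0.

    Returns
    -------
    dict
        ``{"Non-aged": ..., "AA24": ..., "AA48": ..., "AA72": ..., "AA96": ...}``.
    """
    if vis_drop_per_24h < 0 or nir_rise_per_24h < 0:
        raise ParameterError("ageing rates must be >= 0")
    grid = grid or WavelengthGrid()
    wl = np.asarray(grid.wavelengths_nm)
    if len(wl) != base_profile.n_bands:
        raise ParameterError("base profile length does not match the grid")
    vis = (wl >= _VIS_LO) & (wl <= _VIS_HI)
    nir = wl > _VIS_HI
    base = np.asarray(base_profile.mean_reflectance)

    profiles: dict[str, ClassSpectralProfile] = {}
    for name, hours in _AGEING_HOURS.items():
        steps = hours / 24.0
        scale = np.ones_like(base)
        scale[vis] = 1.0 - steps * vis_drop_per_24h
        scale[nir] = 1.0 + steps * nir_rise_per_24h
        means = base * scale
        if (means <= 0).any():
            raise ParameterError(
                f"vis_drop_per_24h={vis_drop_per_24h} drives {name} reflectance <= 0"
            )
        profiles[name] = ClassSpectralProfile(
            name, tuple(means), base_profile.seed_level_sd, base_profile.pixel_noise_sd
        )
    return profiles


@dataclass
class SceneSpec:
    """Geometry and composition of one synthetic petri-dish scene.

    Defaults model a desk-scale dish: 700 x 700 px, 25 seeds of radius
    18–28 px — the full acquisition geometry (2056 x 2056) scaled down so a
    scene renders in well under a second.
    """

    image_size: tuple[int, int] = (700, 700)
    n_seeds: int = 25
    seed_radius_px: tuple[int, int] = (18, 28)
    background_profile: ClassSpectralProfile = field(
        default_factory=default_background_profile
    )
    dish_profile: ClassSpectralProfile = field(default_factory=default_dish_profile)
    seed_classes: Sequence[str] = ("Non-aged",) * 25
    rng_seed: int = 0
    dish_radius_frac: float = 0.45
    eccentricity_range: tuple[float, float] = (1.0, 1.6)
    max_placement_tries: int = 2000
    #: render the dark hilum ("black eye") patch on each seed; off by default
    render_hilum: bool = False
    hilum_reflectance_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.n_seeds < 0:
            raise ParameterError("n_seeds must be >= 0")
        if len(self.seed_classes) != self.n_seeds:
            raise ParameterError(
                f"seed_classes lists {len(self.seed_classes)} entries for "
                f"{self.n_seeds} seeds"
            )
        rmin, rmax = self.seed_radius_px
        if not (0 < rmin <= rmax):
            raise ParameterError("seed_radius_px must satisfy 0 < min <= max")


@dataclass(frozen=True)
class SeedTruth:
    """Ground truth for one rendered seed."""

    seed_id: int
    class_name: str
    rows: np.ndarray  # pixel row coordinates, 0-based
    cols: np.ndarray  # pixel col coordinates, 0-based
    profile: np.ndarray  # the per-seed drawn spectrum (class mean + offset)

    @property
    def area_px(self) -> int:
        return int(self.rows.size)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for a whole scene: per-seed pixel sets and classes."""

    seeds: tuple[SeedTruth, ...]
    dish_center: tuple[float, float]
    dish_radius_px: float

    def seed_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of all seed pixels (union of per-seed pixel sets)."""
        m = np.zeros(shape, dtype=np.uint8)
        for s in self.seeds:
            m[s.rows, s.cols] = 1
        return m

    def classes_for_blobs(self, blobs) -> list[str]:
        """Match recovered blobs to rendered seeds by pixel overlap.

        Returns the true class name per blob, in blob order. Each blob is
        assigned the seed whose pixel set overlaps it most; a blob overlapping
        no seed raises :class:`~seedspectra.exceptions.ValidationError`.
        """
        keyed = {}
        for s in self.seeds:
            for r, c in zip(s.rows, s.cols):
                keyed[(int(r), int(c))] = s.seed_id
        by_id = {s.seed_id: s.class_name for s in self.seeds}
        out = []
        for blob in blobs:
            hits: dict[int, int] = {}
            for r, c in zip(blob.rows, blob.cols):
                sid = keyed.get((int(r), int(c)))
                if sid is not None:
                    hits[sid] = hits.get(sid, 0) + 1
            if not hits:
                raise ValidationError(
                    f"blob {blob.blob_id} overlaps no rendered seed"
                )
            out.append(by_id[max(hits, key=hits.get)])
        return out


def _place_seeds(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping axis-aligned ellipses inside the dish."""
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dish_r = spec.dish_radius_frac * min(h, w)
    rmin, rmax = spec.seed_radius_px
    emin, emax = spec.eccentricity_range
    placed: list[tuple[float, float, float, float]] = []  # (y, x, a, b)
    for _ in range(spec.n_seeds):
        for attempt in range(spec.max_placement_tries):
            a = rng.uniform(rmin, rmax)          # semi-major (rows)
            b = a / rng.uniform(emin, emax)      # semi-minor (cols)
            r_out = max(a, b)
            # uniform position in the dish disk, keeping the ellipse inside
            rad = (dish_r - r_out - 2.0) * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            ok = all(
                np.hypot(y - py, x - px) > r_out + max(pa, pb) + 2.0
                for py, px, pa, pb in placed
            )
            if ok:
                placed.append((y, x, a, b))
                break
        else:
            raise PlacementError(
                f"could not place seed {len(placed) + 1}/{spec.n_seeds} without "
                f"overlap after {spec.max_placement_tries} tries; reduce n_seeds "
                f"or seed_radius_px"
            )
    return placed, (cy, cx), dish_r


def render_scene(
    spec: SceneSpec,
    profiles: Mapping[str, ClassSpectralProfile],
    grid: WavelengthGrid | None = None,
) -> tuple[MultispectralCube, SceneTruth]:
    """Render a labelled petri-dish cube with known per-pixel ground truth.

    The dish is a centred disk of ``spec.dish_profile`` over the background;
    each seed is a filled axis-aligned ellipse at a non-overlapping position.
    Each seed draws a per-seed spectrum (class mean + per-band Gaussian offset
    of SD ``seed_level_sd``) and then per-pixel Gaussian noise of SD
    ``pixel_noise_sd``. With both SDs zero every seed pixel equals the class
    mean exactly, which is what makes exact-recovery tests possible.

    Determinism: all randomness flows from ``spec.rng_seed`` through a single
    generator, so equal specs render bitwise-identical cubes.
    """
    grid = grid or WavelengthGrid()
    n_bands = len(grid)
    for cls in set(spec.seed_classes):
        if cls not in profiles:
            raise ValidationError(f"no spectral profile supplied for class '{cls}'")
        if profiles[cls].n_bands != n_bands:
            raise ValidationError(
                f"profile '{cls}' has {profiles[cls].n_bands} bands, grid has {n_bands}"
            )
    if spec.background_profile.n_bands != n_bands or spec.dish_profile.n_bands != n_bands:
        raise ValidationError("background/dish profile length does not match the grid")

    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    placed, (cy, cx), dish_r = _place_seeds(spec, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    img = np.empty((h, w, n_bands), dtype=np.float32)
    bg = spec.background_profile
    img[:] = np.asarray(bg.mean_reflectance, dtype=np.float32)
    dish_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= dish_r**2
    img[dish_mask] = np.asarray(spec.dish_profile.mean_reflectance, dtype=np.float32)

    # surface noise on background and dish (seed pixels are overwritten below)
    if bg.pixel_noise_sd > 0:
        img[~dish_mask] += rng.normal(0, bg.pixel_noise_sd, ((~dish_mask).sum(), n_bands)).astype(np.float32)
    if spec.dish_profile.pixel_noise_sd > 0:
        img[dish_mask] += rng.normal(
            0, spec.dish_profile.pixel_noise_sd, (int(dish_mask.sum()), n_bands)
        ).astype(np.float32)

    seeds: list[SeedTruth] = []
    for sid, ((y, x, a, b), cls) in enumerate(zip(placed, spec.seed_classes), start=1):
        prof = profiles[cls]
        inside = ((yy - y) / a) ** 2 + ((xx - x) / b) ** 2 <= 1.0
        rows, cols = np.nonzero(inside)
        mean = np.asarray(prof.mean_reflectance, dtype=np.float64)
        drawn = mean + (
            rng.normal(0, prof.seed_level_sd, n_bands) if prof.seed_level_sd > 0 else 0.0
        )
        px = np.broadcast_to(drawn, (rows.size, n_bands)).astype(np.float32).copy()
        if spec.render_hilum:
            # small low-reflectance patch offset toward the seed edge,
            # mimicking the cowpea "black eye"; stresses segmentation but
            # stays inside the seed so ground-truth pixel sets are unchanged
            hy, hx = y + 0.4 * a, x
            hr = 0.25 * min(a, b)
            in_hilum = (rows - hy) ** 2 + (cols - hx) ** 2 <= hr**2
            px[in_hilum] *= spec.hilum_reflectance_scale
        if prof.pixel_noise_sd > 0:
            px = px + rng.normal(0, prof.pixel_noise_sd, (rows.size, n_bands)).astype(
                np.float32
            )
        img[rows, cols] = px
        seeds.append(SeedTruth(sid, cls, rows, cols, np.asarray(drawn)))

    np.clip(img, 1e-6, 1.5, out=img)
    cube = MultispectralCube(img, grid)
    return cube, SceneTruth(tuple(seeds), (cy, cx), dish_r)


# ---------------------------------------------------------------------------
# Seed-lot label model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedLotLabels:
    """Per-seed label table for a synthetic seed lot.

    Columns of :attr:`table`: ``seed_id``, ``ageing_class``, ``germinated``
    (bool), ``germination_start_h`` (NaN when not germinated), ``start_class``
    (Early/Medium/Dead) and ``seedling_class`` (Normal/Abnormal).

    The vigor classes are tied to the germination record: Early means radicle
    protrusion within 48 h of sowing, Medium within 72 h, Dead means no
    germination. Non-germinated seeds are always Abnormal (dead seeds are
    lumped with abnormal seedlings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        germ = t["germinated"].to_numpy(dtype=bool)
        start = t["germination_start_h"].to_numpy(dtype=float)
        sc = t["start_class"].to_numpy()
        if not (np.isnan(start[~germ])).all():
            raise ValidationError("non-germinated seeds must have no start time")
        want = np.where(
            ~germ, "Dead", np.where(start <= 48.0, "Early", np.where(start <= 72.0, "Medium", "Late"))
        )
        if (want == "Late").any():
            raise ValidationError(
                "germination start times beyond 72 h are outside the class taxonomy"
            )
        if (sc != want).any():
            raise ValidationError("start_class inconsistent with germination record")
        if (t.loc[~germ, "seedling_class"] != "Abnormal").any():
            raise ValidationError("non-germinated seeds must be labelled Abnormal")

    def __len__(self) -> int:
        return len(self.table)

    def class_counts(self, column: str) -> pd.Series:
        return self.table[column].value_counts()

    def binary_ageing(self) -> pd.Series:
        """Collapse the five ageing classes to Non-aged vs Aged."""
        return self.table["ageing_class"].map(
            lambda c: "Non-aged" if c == "Non-aged" else "Aged"
        )


def make_labels(
    n_seeds: int = 501,
    ageing_mix: Mapping[str, float] | None = None,
    germ_prob_by_class: Mapping[str, float] | None = None,
    start_time_model: Mapping[str, float] | None = None,
    abnormal_prob_by_class: Mapping[str, float] | None = None,
    rng_seed: int = 0,
) -> SeedLotLabels:
    """Draw a labelled seed lot with the ageing/germination/vigor class taxonomy.

    Parameters
    ----------
    n_seeds
        Lot size; the reference lot composition is 501 seeds.
    ageing_mix
        Proportion of the lot per ageing class; must sum to 1. Default is
        roughly one fifth per class (100/501 non-aged, the rest split evenly).
    germ_prob_by_class
        Germination probability per ageing class. Defaults decrease with
        ageing duration (0.97, 0.90, 0.78, 0.55, 0.35).
    start_time_model
        Log-normal germination-start model: ``median_h`` (median start for
        non-aged seeds), ``sigma`` (log-scale SD) and ``delay_per_24h``
        (multiplicative delay per 24 h of ageing). Draws are truncated to
        (0, 72] h by resampling, matching the observation window after which
        a seed is scored Dead.
    abnormal_prob_by_class
        Probability that a *germinated* seed still yields an abnormal
        seedling, per ageing class. Defaults increase with ageing.
    rng_seed
        Single integer seed; identical seeds give identical lots.
    """
    ageing_mix = dict(
        ageing_mix
        if ageing_mix is not None
        else {"Non-aged": 100 / 501, "AA24": 101 / 501, "AA48": 100 / 501,
              "AA72": 100 / 501, "AA96": 100 / 501}
    )
    if abs(sum(ageing_mix.values()) - 1.0) > 1e-9:
        raise ParameterError("ageing_mix proportions must sum to 1")
    germ_prob_by_class = dict(
        germ_prob_by_class
        if germ_prob_by_class is not None
        else {"Non-aged": 0.97, "AA24": 0.90, "AA48": 0.78, "AA72": 0.55, "AA96": 0.35}
    )
    abnormal_prob_by_class = dict(
        abnormal_prob_by_class
        if abnormal_prob_by_class is not None
        else {"Non-aged": 0.05, "AA24": 0.12, "AA48": 0.22, "AA72": 0.35, "AA96": 0.50}
    )
    stm = {"median_h": 36.0, "sigma": 0.30, "delay_per_24h": 1.12}
    if start_time_model:
        stm.update(start_time_model)
    for m in (germ_prob_by_class, abnormal_prob_by_class):
        for cls, p in m.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"probability for class '{cls}' out of [0, 1]: {p}")

    rng = np.random.default_rng(rng_seed)
    classes = list(ageing_mix)
    # largest-remainder apportionment of the lot across ageing classes
    quotas = np.array([ageing_mix[c] * n_seeds for c in classes])
    counts = np.floor(quotas).astype(int)
    rem = n_seeds - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1

    records = []
    sid = 0
    for cls, n_cls in zip(classes, counts):
        hours = _AGEING_HOURS.get(cls, 0)
        mu = np.log(stm["median_h"]) + (hours / 24.0) * np.log(stm["delay_per_24h"])
        for _ in range(n_cls):
            sid += 1
            germ = rng.uniform() < germ_prob_by_class.get(cls, 0.0)
            if germ:
                t = float(np.exp(rng.normal(mu, stm["sigma"])))
                while t > 72.0:  # beyond the scoring window -> resample
                    t = float(np.exp(rng.normal(mu, stm["sigma"])))
                start_class = "Early" if t <= 48.0 else "Medium"
                abnormal = rng.uniform() < abnormal_prob_by_class.get(cls, 0.0)
                seedling = "Abnormal" if abnormal else "Normal"
            else:
                t, start_class, seedling = float("nan"), "Dead", "Abnormal"
            records.append(
                {
                    "seed_id": sid,
                    "ageing_class": cls,
                    "germinated": germ,
                    "germination_start_h": t,
                    "start_class": start_class,
                    "seedling_class": seedling,
                }
            )
    return SeedLotLabels(pd.DataFrame.from_records(records))
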
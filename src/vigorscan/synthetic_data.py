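"""Synthetic seedling scenes and simulated RIL populations with known truth.

Two generators make the whole pipeline testable without any external data:

* :func:`generate_seedling_image` renders erect green seedling blades on a
  soil-colored background with hard color boundaries (no anti-aliasing) and
  records the exact foreground mask, tip/base rows and pixel area.  Scenes
  default to 512 x 512 so tests run in seconds; segmentation defaults are
  robust at this scale (structuring element well below blade width).

* :func:`simulate_ril_population` draws fully inbred RIL genotypes by a
  chromosome-wise Markov walk with RIL-expanded Haldane recombination between
  adjacent markers, plants additive QTL effects, and scales Gaussian
  replicate noise so a stated line-mean heritability holds in expectation.

:func:`generate_study_fixture` combines both into a desk-scale emulation of
a 162-line, 8-replicate study on a 12-chromosome, 228-marker map, with a
height-like trait controlled by QTL on chromosomes 1, 4 and 12 and a
biomass-like trait sharing only the chromosome-1 locus (planted genetic
correlation 0.66).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qtl_mapping import GeneticMap, GenotypeMatrix, haldane_r, ril_expansion
from .trait_extraction import TraitRecord

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "SimulatedPopulation",
    "StudyFixture",
    "generate_seedling_image",
    "default_genetic_map",
    "simulate_ril_population",
    "generate_study_fixture",
]


@dataclass(frozen=True)
class SceneParams:
    """Rendering knobs for a synthetic seedling scene.

    Blades rise quasi-vertically from a base row near the frame bottom; each
    blade gets its own length, width, slant and jittered green shade.  The
    background is a flat soil brown, optionally salted with single green
    noise pixels at ``noise_rate`` (fraction of background pixels).
    """

    height: int = 512
    width: int = 512
    n_blades: int = 3
    blade_length_range: tuple[int, int] = (150, 300)
    blade_width_range: tuple[int, int] = (4, 8)
    base_row: int = 460
    green_rgb: tuple[int, int, int] = (60, 170, 60)
    hue_jitter: int = 25
    background_rgb: tuple[int, int, int] = (110, 84, 58)
    noise_rate: float = 0.0002

    def __post_init__(self) -> None:
        if self.height > 1024 or self.width > 1024:
            raise ValueError("scene must be at most 1024 x 1024")
        if not 1 <= self.n_blades <= 5:
            raise ValueError("n_blades must be in [1, 5]")
        if self.blade_length_range[1] > self.base_row:
            raise ValueError("blades would exceed the frame")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene plus its exact per-pixel and row-level ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    truth_tip_row: int
    truth_base_row: int
    truth_area_px: int
    seed: int


@dataclass(frozen=True)
class SimulatedPopulation:
    """RIL genotypes and replicated phenotypes with planted QTL."""

    gmap: GeneticMap
    genotypes: GenotypeMatrix
    planted_qtl: tuple[tuple[str, float, float], ...]  # (chromosome, position_cM, effect)
    phenotypes: tuple[TraitRecord, ...]
    heritability: float
    seed: int
    genetic_values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class StudyFixture:
    """Paired imaging + mapping fixture emulating the full study shape."""

    scenes: tuple[SyntheticScene, ...]
    population: SimulatedPopulation
    fw_records: tuple[TraitRecord, ...]
    fw_qtl: tuple[tuple[str, float, float], ...]
    genetic_values_ph: np.ndarray
    genetic_values_fw: np.ndarray


def generate_seedling_image(seed: int, params: SceneParams | None = None) -> SyntheticScene:
    """Render one seedling scene deterministically from (seed, params)."""
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.array(params.background_rgb, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=bool)

    lo_len, hi_len = params.blade_length_range
    lo_w, hi_w = params.blade_width_range
    # spread blade anchor columns around the frame center
    centers = np.linspace(w * 0.3, w * 0.7, params.n_blades) + rng.integers(-15, 16, params.n_blades)
    for c in centers:
        length = int(rng.integers(lo_len, hi_len + 1))
        width = int(rng.integers(lo_w, hi_w + 1))
        slant = rng.uniform(-0.25, 0.25)  # px of horizontal drift per row
        g = np.array(params.green_rgb, dtype=np.int64)
        g[0] = np.clip(g[0] + rng.integers(-params.hue_jitter, params.hue_jitter + 1), 0, 255)
        g[2] = np.clip(g[2] + rng.integers(-params.hue_jitter, params.hue_jitter + 1), 0, 255)
        color = g.astype(np.uint8)
        for k in range(length):
            row = params.base_row - k
            # taper the top few rows to a blunt 3-px tip (the structuring
            # element cannot preserve features narrower than itself)
            cur_w = width if k < length - 3 else max(3, width - (k - (length - 4)))
            col = int(round(c + slant * k))
            c0 = max(0, col - cur_w // 2)
            c1 = min(w, c0 + cur_w)
            img[row, c0:c1] = color
            mask[row, c0:c1] = True

    if params.noise_rate > 0:
        bg = ~mask
        n_noise = int(round(params.noise_rate * bg.sum()))
        if n_noise:
            flat = np.flatnonzero(bg)
            pick = rng.choice(flat, size=n_noise, replace=False)
            rr, cc = np.unravel_index(pick, mask.shape)
            img[rr, cc] = np.array(params.green_rgb, dtype=np.uint8)

    rows = np.flatnonzero(mask.any(axis=1))
    return SyntheticScene(
        image=img,
        truth_mask=mask,
        truth_tip_row=int(rows[0]),
        truth_base_row=int(rows[-1]),
        truth_area_px=int(mask.sum()),
        seed=seed,
    )


def default_genetic_map(n_chromosomes: int = 12, markers_per_chromosome: int = 19, spacing_cM: float = 6.0) -> GeneticMap:
    """Equally spaced fixture map: 12 chromosomes x 19 markers = 228 by default."""
    names, chroms, pos = [], [], []
    for c in range(1, n_chromosomes + 1):
        for m in range(markers_per_chromosome):
            names.append(f"C{c}M{m + 1:02d}")
            chroms.append(str(c))
            pos.append(m * spacing_cM)
    return GeneticMap(names=tuple(names), chromosomes=tuple(chroms), positions_cM=tuple(pos))


def _simulate_genotypes(rng: np.random.Generator, n_lines: int, gmap: GeneticMap) -> GenotypeMatrix:
    """Markov walk per chromosome with RIL-expanded Haldane transition probabilities."""
    chroms = np.asarray(gmap.chromosomes, dtype=object)
    pos = np.asarray(gmap.positions_cM)
    calls = np.empty((n_lines, gmap.n_markers))
    for chrom in gmap.chromosome_order():
        sel = np.flatnonzero(chroms == chrom)
        big_r = ril_expansion(haldane_r(np.diff(pos[sel])))
        g = rng.random(n_lines) < 0.5
        calls[:, sel[0]] = g
        for j, r in zip(sel[1:], big_r):
            g = g ^ (rng.random(n_lines) < r)
            calls[:, j] = g
    return GenotypeMatrix(line_ids=tuple(f"RIL{i + 1:03d}" for i in range(n_lines)), calls=calls)


def _marker_index_at(gmap: GeneticMap, chrom: str, pos_cM: float) -> int:
    """Index of the map marker nearest to (chrom, pos); error if off-map."""
    chroms = np.asarray(gmap.chromosomes, dtype=object)
    sel = np.flatnonzero(chroms == str(chrom))
    if sel.size == 0:
        raise ValueError(f"QTL chromosome {chrom!r} not on the map")
    pos = np.asarray(gmap.positions_cM)[sel]
    if not pos[0] <= pos_cM <= pos[-1]:
        raise ValueError(f"QTL position {pos_cM} cM outside chromosome {chrom!r} span [{pos[0]}, {pos[-1]}]")
    return int(sel[np.argmin(np.abs(pos - pos_cM))])


def _genetic_values(gmap: GeneticMap, geno: GenotypeMatrix, qtl: list[tuple[str, float, float]]) -> np.ndarray:
    """Sum of planted additive effects with genotypes coded AA=+1, BB=-1.

    A planted QTL acts through the marker nearest its stated position.
    """
    g = np.zeros(geno.n_lines)
    for chrom, pos_cM, effect in qtl:
        j = _marker_index_at(gmap, chrom, pos_cM)
        g += effect * (2.0 * geno.calls[:, j] - 1.0)
    return g


def simulate_ril_population(
    seed: int,
    n_lines: int = 162,
    gmap: GeneticMap | None = None,
    qtl: list[tuple[str, float, float]] | None = None,
    heritability: float = 0.5,
    n_reps: int = 8,
    trait: str = "PH_mm",
    mean: float = 200.0,
) -> SimulatedPopulation:
    """Simulate a RIL population with planted additive QTL.

    ``qtl`` is a list of (chromosome, position_cM, additive_effect); effects
    act on the +1/-1 genotype axis.  Replicate noise is Gaussian with SD
    chosen so the heritability of line means (over n_reps replicates) equals
    ``heritability`` against the empirical genetic variance.  Trait values
    are clipped at 0 to respect the trait-record domain; with the default
    mean and effect scales clipping is never active in practice.
    """
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must lie in (0, 1]")
    if gmap is None:
        gmap = default_genetic_map()
    if qtl is None:
        qtl = [("1", 48.0, 5.0)]
    rng = np.random.default_rng(seed)
    geno = _simulate_genotypes(rng, n_lines, gmap)
    g = _genetic_values(gmap, geno, qtl)
    var_g = float(np.var(g))
    if var_g == 0.0:
        sd_e = 1.0  # null architecture: pure-noise phenotype on a unit scale
    elif heritability < 1.0:
        sd_e = float(np.sqrt(n_reps * var_g * (1.0 - heritability) / heritability))
    else:
        sd_e = 0.0
    records: list[TraitRecord] = []
    for i, lid in enumerate(geno.line_ids):
        noise = rng.normal(0.0, sd_e, n_reps) if sd_e > 0 else np.zeros(n_reps)
        for rep in range(1, n_reps + 1):
            value = max(0.0, mean + g[i] + noise[rep - 1])
            records.append(TraitRecord(lid, rep, trait, value))
    return SimulatedPopulation(
        gmap=gmap,
        genotypes=geno,
        planted_qtl=tuple((str(c), float(p), float(e)) for c, p, e in qtl),
        phenotypes=tuple(records),
        heritability=heritability,
        seed=seed,
        genetic_values=g,
    )


#: Fig-1-like architecture: height QTL on chromosomes 1, 4 and 12; the
#: chromosome-1 locus carries the largest share so a biomass-like trait
#: acting through it alone can reach the 0.66 planted genetic correlation.
DEFAULT_PH_QTL: tuple[tuple[str, float, float], ...] = (("1", 48.0, 6.0), ("4", 36.0, 3.5), ("12", 60.0, 3.5))


def generate_study_fixture(
    seed: int,
    n_lines: int = 162,
    n_reps: int = 8,
    heritability: float = 0.5,
    n_scenes: int = 12,
    scene_size: int = 256,
    target_genetic_r: float = 0.66,
) -> StudyFixture:
    """Desk-scale paired fixture: seedling scenes + a mapped RIL population.

    The height-like trait (PH_mm) has QTL on chromosomes 1, 4 and 12; the
    biomass-like trait (FW_g) acts through the chromosome-1 locus only, with
    a polygenic background sized so the planted correlation between the two
    genetic-value vectors is ``target_genetic_r`` in expectation.
    """
    pop = simulate_ril_population(
        seed,
        n_lines=n_lines,
        qtl=list(DEFAULT_PH_QTL),
        heritability=heritability,
        n_reps=n_reps,
        trait="PH_mm",
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]).generate_state(1)[0])

    a1, a4, a12 = (q[2] for q in DEFAULT_PH_QTL)
    var_ph = a1**2 + a4**2 + a12**2
    # corr(g_ph, g_fw) = a1*b / (sqrt(var_ph) * sqrt(b^2 + c^2)); solve for the
    # polygenic SD c given a chromosome-1 effect b of the same size as a1
    share = target_genetic_r * np.sqrt(var_ph) / a1
    if share >= 1.0:
        raise ValueError("target genetic correlation unreachable with this architecture")
    b = a1 * 0.4  # FW effect on its own scale (g-like units)
    c = b * np.sqrt(1.0 / share**2 - 1.0)
    fw_qtl = [("1", 48.0, float(b))]
    g_fw = _genetic_values(pop.gmap, pop.genotypes, fw_qtl) + rng.normal(0.0, c, n_lines)
    var_gfw = float(np.var(g_fw))
    sd_e_fw = float(np.sqrt(n_reps * var_gfw * (1.0 - heritability) / heritability)) if heritability < 1.0 else 0.0
    fw_records: list[TraitRecord] = []
    for i, lid in enumerate(pop.genotypes.line_ids):
        noise = rng.normal(0.0, sd_e_fw, n_reps) if sd_e_fw > 0 else np.zeros(n_reps)
        for rep in range(1, n_reps + 1):
            fw_records.append(TraitRecord(lid, rep, "FW_g", max(0.0, 30.0 + g_fw[i] + noise[rep - 1])))

    scene_params = SceneParams(
        height=scene_size,
        width=scene_size,
        n_blades=2,
        blade_length_range=(80, 160),
        blade_width_range=(4, 7),
        base_row=scene_size - 40,
    )
    seeds = np.random.SeedSequence([seed, 11]).generate_state(n_scenes) % (2**31)
    scenes = tuple(generate_seedling_image(int(s), scene_params) for s in seeds)
    return StudyFixture(
        scenes=scenes,
        population=pop,
        fw_records=tuple(fw_records),
        fw_qtl=tuple((str(cc), float(pp), float(ee)) for cc, pp, ee in fw_qtl),
        genetic_values_ph=pop.genetic_values,
        genetic_values_fw=g_fw,
    )
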
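"""Synthetic ground-truth data for every pipeline stage.

Generates (i) multi-channel nucleus images — an elliptical nucleus with
bright chromocenters over a euchromatic background, early-S (many small
puncta) or late-S (few large chromocenter-associated foci) PCNA patterns,
and a protein channel with a configurable fold-enrichment at replication
foci, under a Poisson + Gaussian camera-noise model on the 16-bit scale;
(ii) FRAP traces with known rate constants, immobile fraction and
acquisition bleaching; (iii) gel images with known integrated band
densities; (iv) GluMS-PCR digest panels from known (5mC, 5hmC) levels; and
(v) bisulfite/TAB clone sets drawn from per-CpG modification probabilities.

Every generator is deterministic given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .frap import FrapTrace
from .glums import DigestPanel
from .io import MAX_UINT16, NucleusImage


class PlacementError(RuntimeError):
    """Chromocenters could not be placed without overlap."""


class ParameterError(ValueError):
    """Invalid simulation parameters."""


class GeometryError(ValueError):
    """Invalid gel lane geometry."""


# ---------------------------------------------------------------------------
# Nucleus images
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    """Parameters of one synthetic nucleus image.

    Intensity levels are noiseless means in 16-bit arbitrary units; the
    camera model applies Poisson noise on the photon-scaled signal
    (``photons = signal / camera_gain``) plus additive Gaussian read noise,
    then clips to [0, 65535].  ``accumulation_fold`` multiplies the protein
    base level inside replication foci.
    """

    image_shape: Tuple[int, int] = (256, 256)
    center: Optional[Tuple[float, float]] = None  # (y, x); default = middle
    semi_axes: Tuple[float, float] = (70.0, 90.0)  # (y, x)
    background_level: float = 500.0
    euchromatin_level: float = 5000.0
    n_chromocenters: int = 6
    chromocenter_radius: Tuple[float, float] = (5.0, 9.0)
    chromocenter_level: float = 20000.0
    pcna_pattern: str = "lateS"  # earlyS | lateS | none
    pcna_background: float = 100.0
    pcna_base_level: float = 1500.0
    pcna_focus_level: float = 12000.0
    n_puncta: int = 60  # early-S puncta
    puncta_radius: Tuple[float, float] = (1.0, 2.0)
    protein_background: float = 100.0
    protein_base_level: float = 3000.0
    accumulation_fold: float = 1.0
    camera_gain: float = 10.0  # AU per photon; 0 disables Poisson noise
    read_noise_sd: float = 50.0  # AU; 0 disables Gaussian noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.accumulation_fold < 0:
            raise ParameterError("accumulation_fold must be >= 0")
        if self.pcna_pattern not in ("earlyS", "lateS", "none"):
            raise ParameterError(f"unknown pcna_pattern {self.pcna_pattern!r}")
        if self.chromocenter_radius[0] > self.chromocenter_radius[1]:
            raise ParameterError("chromocenter radius range reversed")
        levels = (
            self.background_level,
            self.euchromatin_level,
            self.chromocenter_level,
            self.protein_base_level * max(self.accumulation_fold, 1.0),
            self.pcna_focus_level,
        )
        if min(levels) < 0 or max(levels) > MAX_UINT16:
            raise ParameterError("intensity levels outside the 16-bit range")


@dataclass
class GroundTruth:
    """Noiseless truth accompanying a simulated nucleus."""

    nuclear: np.ndarray
    heterochromatin: np.ndarray
    nucleoplasm: np.ndarray
    foci: np.ndarray  # replication-foci mask (protein-enriched region)
    foci_centers: List[Tuple[float, float]]
    accumulation_fold: float
    compaction_fractions: Dict[str, float]

    def __post_init__(self) -> None:
        assert not np.any(self.heterochromatin & ~self.nuclear)
        assert np.array_equal(
            self.nucleoplasm, self.nuclear & ~self.heterochromatin
        )


def _disk(shape: Tuple[int, int], center: Tuple[float, float], radius: float
          ) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(shape: Tuple[int, int], center: Tuple[float, float],
             semi_axes: Tuple[float, float]) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / semi_axes[0]) ** 2 + (
        (xx - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _place_chromocenters(
    spec: NucleusSpec, center: Tuple[float, float], rng: np.random.Generator
) -> List[Tuple[Tuple[float, float], float]]:
    """Rejection-sample non-overlapping chromocenter disks inside the nucleus."""
    placed: List[Tuple[Tuple[float, float], float]] = []
    margin = 2.0
    for _ in range(spec.n_chromocenters):
        r = rng.uniform(*spec.chromocenter_radius)
        ok = False
        for _attempt in range(500):
            # uniform in the ellipse shrunk so the disk stays inside
            ay = spec.semi_axes[0] - r - margin
            ax = spec.semi_axes[1] - r - margin
            if ay <= 0 or ax <= 0:
                break
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1:
                continue
            cy, cx = center[0] + u * ay, center[1] + v * ax
            if all(
                (cy - p[0][0]) ** 2 + (cx - p[0][1]) ** 2
                > (r + p[1] + 2.0) ** 2
                for p in placed
            ):
                placed.append(((cy, cx), r))
                ok = True
                break
        if not ok:
            raise PlacementError(
                "could not place chromocenters without overlap"
            )
    return placed


def _apply_camera_noise(
    signal: np.ndarray, spec: NucleusSpec, rng: np.random.Generator
) -> np.ndarray:
    out = signal.astype(float)
    if spec.camera_gain > 0:
        out = rng.poisson(out / spec.camera_gain) * spec.camera_gain
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.clip(np.rint(out), 0, MAX_UINT16).astype(np.uint16)


def generate_nucleus(spec: NucleusSpec) -> Tuple[NucleusImage, GroundTruth]:
    """Render one synthetic nucleus with DNA, PCNA and protein channels.

    The noiseless protein channel equals ``protein_base_level`` everywhere
    inside the nucleus except inside replication foci, where it equals
    ``accumulation_fold`` times the base level — so the true enrichment
    ratio of the construction is exactly the requested fold.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.image_shape
    center = spec.center or ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    nuclear = _ellipse(shape, center, spec.semi_axes)
    ccs = _place_chromocenters(spec, center, rng)
    het = np.zeros(shape, dtype=bool)
    for c, r in ccs:
        het |= _disk(shape, c, r)
    het &= nuclear
    nucleoplasm = nuclear & ~het

    dna = np.full(shape, spec.background_level)
    dna[nuclear] = spec.euchromatin_level
    dna[het] = spec.chromocenter_level

    pcna = np.full(shape, spec.pcna_background)
    pcna[nuclear] = spec.pcna_base_level
    foci = np.zeros(shape, dtype=bool)
    centers: List[Tuple[float, float]] = []
    if spec.pcna_pattern == "lateS":
        # foci = chromocenter footprints dilated by 1 px
        for c, r in ccs:
            foci |= _disk(shape, c, r + 1.0)
            centers.append(c)
        foci &= nuclear
        pcna[foci] = spec.pcna_focus_level
    elif spec.pcna_pattern == "earlyS":
        for _ in range(spec.n_puncta):
            r = rng.uniform(*spec.puncta_radius)
            for _attempt in range(200):
                cy = rng.uniform(0, shape[0] - 1)
                cx = rng.uniform(0, shape[1] - 1)
                if nucleoplasm[int(round(cy)), int(round(cx))]:
                    foci |= _disk(shape, (cy, cx), r)
                    centers.append((cy, cx))
                    break
        foci &= nuclear
        pcna[foci] = spec.pcna_focus_level

    protein = np.full(shape, spec.protein_background)
    protein[nuclear] = spec.protein_base_level
    protein[foci] = spec.accumulation_fold * spec.protein_base_level

    channels = {
        "dna": _apply_camera_noise(dna, spec, rng),
        "pcna": _apply_camera_noise(pcna, spec, rng),
        "protein": _apply_camera_noise(protein, spec, rng),
    }
    img = NucleusImage(channels=channels, is_projection=True)

    n_nuc = int(nuclear.sum())
    truth = GroundTruth(
        nuclear=nuclear,
        heterochromatin=het,
        nucleoplasm=nucleoplasm,
        foci=foci,
        foci_centers=centers,
        accumulation_fold=spec.accumulation_fold,
        compaction_fractions={
            "euchromatin": float((nuclear & ~het).sum()) / n_nuc,
            "chromocenter": float(het.sum()) / n_nuc,
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclass
class FrapSpec:
    """Parameters of a simulated FRAP recovery.

    The normalized recovery is ``N(t) = plateau - a1 exp(-k1 t)
    - a2 exp(-k2 t)`` from the bleach, with ``a1 + a2 = plateau -
    bleach_depth``.  Acquisition bleaching multiplies the fluorescent
    signal of both nuclear ROIs by a shared slow mono-exponential decay
    losing ``acquisition_bleach`` of the signal over the whole trace.
    ``noise_sd`` is relative (fraction of each ROI's raw scale).
    """

    plateau: float = 0.9  # I_E, fraction of pre-bleach
    bleach_depth: float = 0.2  # I_0, value right after the bleach
    k1: float = 0.2  # s^-1
    k2: float = 0.0
    a1_fraction: float = 1.0  # share of total amplitude on component 1
    n_prebleach: int = 10
    n_postbleach: int = 100
    frame_interval: float = 0.25  # s
    roi1_scale: float = 1000.0
    roi2_scale: float = 2000.0
    background: float = 100.0
    acquisition_bleach: float = 0.0  # fraction of ROI2 lost over the trace
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.plateau <= 1:
            raise ParameterError("plateau must be in (0, 1]")
        if not 0 <= self.bleach_depth < self.plateau:
            raise ParameterError("bleach_depth must be in [0, plateau)")
        if self.k1 <= 0 or self.k2 < 0:
            raise ParameterError("need k1 > 0 and k2 >= 0")
        if not 0 <= self.a1_fraction <= 1:
            raise ParameterError("a1_fraction must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ParameterError("frame interval must be positive")
        if not 0 <= self.acquisition_bleach < 1:
            raise ParameterError("acquisition_bleach must be in [0, 1)")

    @property
    def amplitudes(self) -> Tuple[float, float]:
        total = self.plateau - self.bleach_depth
        return total * self.a1_fraction, total * (1 - self.a1_fraction)


def generate_frap_trace(spec: FrapSpec) -> FrapTrace:
    """Simulate raw ROI1/ROI2/ROI3 intensities for one FRAP experiment."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_prebleach + spec.n_postbleach
    t = np.arange(n) * spec.frame_interval

    signal = np.ones(n)
    tp = t[spec.n_prebleach:] - t[spec.n_prebleach]
    a1, a2 = spec.amplitudes
    signal[spec.n_prebleach:] = (
        spec.plateau - a1 * np.exp(-spec.k1 * tp) - a2 * np.exp(-spec.k2 * tp)
    )

    if spec.acquisition_bleach > 0:
        kb = -np.log(1 - spec.acquisition_bleach) / t[-1]
        decay = np.exp(-kb * t)
    else:
        decay = np.ones(n)

    roi1 = spec.background + spec.roi1_scale * signal * decay
    roi2 = spec.background + spec.roi2_scale * decay
    roi3 = np.full(n, spec.background)
    if spec.noise_sd > 0:
        roi1 = roi1 + rng.normal(0, spec.noise_sd * spec.roi1_scale, n)
        roi2 = roi2 + rng.normal(0, spec.noise_sd * spec.roi2_scale, n)
        roi3 = roi3 + rng.normal(0, spec.noise_sd * spec.background, n)
    return FrapTrace(
        time=t, roi1=roi1, roi2=roi2, roi3=roi3,
        n_prebleach=spec.n_prebleach,
    )


# ---------------------------------------------------------------------------
# Gels and digest panels
# ---------------------------------------------------------------------------

def generate_gel(
    band_densities: Sequence[float],
    shape: Tuple[int, int] = (200, 0),
    lane_width: int = 24,
    lane_pitch: int = 40,
    band_row: float = 100.0,
    band_sigma: float = 5.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> Tuple[np.ndarray, List[Tuple[int, int, int, int]]]:
    """Render a grayscale gel with one Gaussian-profile band per lane.

    Each band's integrated background-subtracted density equals the
    requested value exactly before noise.  Returns the image and the lane
    rectangles ``(row_start, row_stop, col_start, col_stop)`` enclosing
    each band.
    """
    densities = np.asarray(band_densities, dtype=float)
    if np.any(densities < 0):
        raise ParameterError("band densities must be >= 0")
    if lane_width > lane_pitch:
        raise GeometryError("lane_width exceeds lane_pitch: lanes overlap")
    n_lanes = densities.size
    height = shape[0]
    width = max(shape[1], n_lanes * lane_pitch)
    rng = np.random.default_rng(rng_seed)

    img = np.full((height, width), background, dtype=float)
    rows = np.arange(height)
    profile = np.exp(-((rows - band_row) ** 2) / (2 * band_sigma**2))
    rects: List[Tuple[int, int, int, int]] = []
    for i, d in enumerate(densities):
        x0 = i * lane_pitch + (lane_pitch - lane_width) // 2
        x1 = x0 + lane_width
        kernel = np.outer(profile, np.ones(lane_width))
        img[:, x0:x1] += d * kernel / kernel.sum()
        r0 = max(int(band_row - 6 * band_sigma), 0)
        r1 = min(int(band_row + 6 * band_sigma) + 1, height)
        rects.append((r0, r1, x0, x1))
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return img, rects


def generate_panel(
    mc_level: float,
    hmc_level: float,
    d0: float = 1000.0,
    noise_cv: float = 0.0,
    rng_seed: int = 0,
) -> DigestPanel:
    """GluMS-PCR digest panel from known 5mC / 5hmC fractions.

    Band survival follows the cleavage rules of the assay: MspI cleaves
    unmodified C, 5mC and 5hmC but not glucosylated 5hmC (5ghmC), so the
    −BGT MspI band is empty and the +BGT MspI band is proportional to the
    5hmC fraction; HpaII cleaves only unmodified sites, so its band is
    proportional to 5mC + 5hmC.  ``noise_cv`` applies multiplicative
    Gaussian noise to each measured density.
    """
    if not (0 <= mc_level <= 1 and 0 <= hmc_level <= 1
            and mc_level + hmc_level <= 1):
        raise ParameterError("mc/hmc levels must be fractions summing <= 1")
    if d0 <= 0:
        raise ParameterError("undigested control density must be positive")
    rng = np.random.default_rng(rng_seed)
    dm = 0.0
    dg = hmc_level * d0
    dh = (mc_level + hmc_level) * d0
    vals = np.array([d0, dm, dg, dh])
    if noise_cv > 0:
        vals = np.clip(vals * (1 + rng.normal(0, noise_cv, 4)), 0, None)
    return DigestPanel(
        undigested=float(vals[0]),
        mspi_minus_bgt=float(vals[1]),
        mspi_plus_bgt=float(vals[2]),
        hpaii=float(vals[3]),
        sample_id="synthetic",
    )


# ---------------------------------------------------------------------------
# Bisulfite / TAB clone sets
# ---------------------------------------------------------------------------

#: Synthetic 150-bp amplicon (fixed, not from any genome) with 8 CpG sites.
DEFAULT_AMPLICON = (
    "ATTGACGGTA" "CCATTCGATA" "GGTACCGTTA" "TTAGGCTTCA" "ACGTTAGCTA"
    "GGATCCGATT" "ACCTTAGGCA" "TTCGGATACA" "GGTTACGTAC" "CATTAGGATC"
    "AACGGTATTC" "AGGCTTACCA" "TTGGACCATA" "GGCATTACCT" "TAGGCATTCA"
)


@dataclass
class CloneSpec:
    """Parameters of a simulated bisulfite / TAB clone set.

    ``p_mc`` and ``p_hmc`` give the per-CpG probability that the cytosine
    carries 5mC or 5hmC (scalar, or one value per CpG site in reference
    order).  ``conversion`` is the bisulfite conversion efficiency for
    unprotected cytosines; TAB chemistry additionally has a glucosylation
    protection efficiency for 5hmC and a Tet-oxidation efficiency for 5mC.
    """

    reference: str = DEFAULT_AMPLICON
    p_mc: float | Sequence[float] = 0.5
    p_hmc: float | Sequence[float] = 0.3
    n_clones: int = 20
    conversion: float = 1.0
    chemistry: str = "BS"  # BS | TAB
    protection: float = 1.0  # TAB: P(5hmC glucosyl-protected)
    oxidation: float = 1.0  # TAB: P(5mC oxidized to 5caC)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ParameterError("n_clones must be >= 1")
        if self.chemistry not in ("BS", "TAB"):
            raise ParameterError(f"unknown chemistry {self.chemistry!r}")
        for p in (self.conversion, self.protection, self.oxidation):
            if not 0 <= p <= 1:
                raise ParameterError("efficiencies must lie in [0, 1]")
        pos = cpg_positions(self.reference)
        if not pos:
            raise ParameterError("reference contains no CpG site")
        pm = np.broadcast_to(np.asarray(self.p_mc, float), (len(pos),))
        ph = np.broadcast_to(np.asarray(self.p_hmc, float), (len(pos),))
        if np.any(pm < 0) or np.any(ph < 0) or np.any(pm + ph > 1):
            raise ParameterError("need p_mc, p_hmc >= 0 and p_mc + p_hmc <= 1")

    @property
    def site_probs(self) -> Tuple[np.ndarray, np.ndarray]:
        n = len(cpg_positions(self.reference))
        return (
            np.broadcast_to(np.asarray(self.p_mc, float), (n,)).copy(),
            np.broadcast_to(np.asarray(self.p_hmc, float), (n,)).copy(),
        )


def cpg_positions(reference: str) -> List[int]:
    """0-based indices of the C of each CpG dinucleotide."""
    ref = reference.upper()
    return [i for i in range(len(ref) - 1) if ref[i: i + 2] == "CG"]


@dataclass
class CloneTruth:
    """Ground truth for a simulated clone set."""

    cpg_positions: List[int]
    states: np.ndarray  # clones x sites, values 'C' | 'mC' | 'hmC'
    emitted: np.ndarray  # clones x sites, emitted base 'C' | 'T'


def _emit_cpg(state: str, spec: CloneSpec, rng: np.random.Generator) -> str:
    """Base read at a CpG cytosine after conversion chemistry and PCR."""
    c = spec.conversion
    if spec.chemistry == "BS":
        if state in ("mC", "hmC"):  # 5mC and 5hmC resist conversion
            return "C"
        return "T" if rng.random() < c else "C"
    # TAB: only glucosyl-protected 5hmC reads C
    if state == "hmC":
        if rng.random() < spec.protection:
            return "C"
        return "T" if rng.random() < c else "C"
    if state == "mC":
        if rng.random() < spec.oxidation:  # oxidized to 5caC, then converted
            return "T" if rng.random() < c else "C"
        return "C"  # unoxidized 5mC resists bisulfite
    return "T" if rng.random() < c else "C"


def generate_clones(
    spec: CloneSpec,
) -> Tuple[List[SeqRecord], CloneTruth]:
    """Draw per-CpG modification states and emit converted clone sequences.

    Non-CpG cytosines are unmodified and convert to T with the spec's
    conversion efficiency under both chemistries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ref = spec.reference.upper()
    pos = cpg_positions(ref)
    pm, ph = spec.site_probs
    pu = 1.0 - pm - ph

    records: List[SeqRecord] = []
    states = np.empty((spec.n_clones, len(pos)), dtype=object)
    emitted = np.empty((spec.n_clones, len(pos)), dtype=object)
    state_names = np.array(["C", "mC", "hmC"], dtype=object)
    for i in range(spec.n_clones):
        seq = list(ref)
        for j, p in enumerate(pos):
            state = state_names[
                rng.choice(3, p=[pu[j], pm[j], ph[j]])
            ]
            base = _emit_cpg(state, spec, rng)
            states[i, j] = state
            emitted[i, j] = base
            seq[p] = base
        for k, b in enumerate(seq):
            if b == "C" and k not in pos:
                seq[k] = "T" if rng.random() < spec.conversion else "C"
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=f"clone_{i:03d}",
                description=f"{spec.chemistry} synthetic clone",
            )
        )
    return records, CloneTruth(
        cpg_positions=pos, states=states, emitted=emitted
    )
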
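"""Seeded generators for every input the pipeline consumes.

The spine generator emulates longitudinal two-photon observations of apical
tuft branchlets: linear dendrites ~30 µm long carrying spines at a baseline
density, observed over k sessions at 3-day spacing.  Between sessions each
spine is eliminated with a per-interval probability (optionally biased
toward small spines), and new spines appear with a per-interval probability
per existing spine.  A tunable clustering bias ``cluster_bias`` places a
fraction of new spines within ``cluster_scale_um`` of another new spine of
the same interval; with the bias at 0 new spines are uniform on the
branchlet, which is the null hypothesis of the clustering test.

Group presets follow the reported 3-day rates: generation/elimination
5.3%/8.0% for unexposed (UE) controls and 10.2%/12.5% for VPA-exposed
animals.

The axon generator produces 1-D intensity profiles along axons: baseline 1,
Gaussian bumps (sigma ~0.5 µm) at bouton positions whose peak-to-backbone
amplitude ratio is >=2 for true boutons, plus optional sub-threshold decoy
bumps and i.i.d. Gaussian noise.  The z-stack generator builds small 3-D
fluorescence stacks (51 planes at 0.5 µm) from spherical blobs over a
cylindrical shaft, for the volume-quantification stage.  The logFC
generator emits paired differential-expression tables structured into gene
modules with a configurable concordant fraction.

All generators draw from child streams of a single root seed, so outputs
are byte-reproducible and independent of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Axon, AxonDataset, Dendrite, SpineDataset, SpineRecord

__all__ = [
    "SimulationConfig",
    "AxonSimConfig",
    "ConcordanceSimConfig",
    "UE_PRESET",
    "VPA_PRESET",
    "generate_spine_dataset",
    "generate_axon_profiles",
    "generate_zstack",
    "generate_logfc_tables",
]


def _child(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the longitudinal spine-dataset generator.

    Defaults reproduce the control-group imaging conditions: branchlet span
    31.7 ± 5.9 µm, three sessions 3 days apart, UE generation/elimination
    rates.  ``elimination_volume_coeff`` > 0 tilts elimination toward small
    spines on the log-volume scale (log-odds per unit of
    ``volume_logmean - log V``).
    """

    n_dendrites: int = 12
    dendrite_length_mean_um: float = 31.7
    dendrite_length_sd_um: float = 5.9
    baseline_density_per_um: float = 0.6
    p_generate: float = 0.053
    p_eliminate: float = 0.080
    cluster_bias: float = 0.0          # pi_c: P(new spine is placed near another new spine)
    cluster_scale_um: float = 3.0      # delta_c
    n_sessions: int = 3
    volume_logmean: float = -1.2       # median normalized volume ~0.30
    volume_logsd: float = 0.8
    elimination_volume_coeff: float = 0.0
    group: str = "UE"
    animal_id: str = "sim"
    seed: int = 0

    def validated(self) -> "SimulationConfig":
        for name in ("p_generate", "p_eliminate", "cluster_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dendrite_length_mean_um <= 0 or self.dendrite_length_sd_um < 0:
            raise ValueError("dendrite length parameters must be positive")
        if self.cluster_scale_um > self.dendrite_length_mean_um:
            raise ValueError(
                "cluster_scale_um exceeds the mean dendrite length: "
                "clustered placement cannot fit on the branchlet"
            )
        if self.n_sessions < 2:
            raise ValueError("need at least two sessions")
        return self


UE_PRESET = SimulationConfig(p_generate=0.053, p_eliminate=0.080, group="UE")
VPA_PRESET = SimulationConfig(p_generate=0.102, p_eliminate=0.125, group="VPA")


def generate_spine_dataset(config: SimulationConfig) -> SpineDataset:
    """Simulate a k-session spine dataset under a birth/death point process.

    Session-1 spines: Poisson(density*L) count, uniform positions.  Each
    interval: every present spine dies with probability
    ``sigmoid(logit(p_eliminate) + coeff*(volume_logmean - log V))``; new
    spines number Binomial(n_present, p_generate), each placed near a
    previously placed new spine of the same interval with probability
    ``cluster_bias`` (uniform within ±cluster_scale_um, clipped to the
    branchlet), otherwise uniform.  Volumes are log-normal and fixed at
    birth.
    """
    config = config.validated()
    rng = _child(config.seed, 0)
    dendrites: list[Dendrite] = []
    spines: list[SpineRecord] = []
    k = config.n_sessions
    eps = 1e-12
    logit_elim = math.log(
        max(config.p_eliminate, eps) / max(1 - config.p_eliminate, eps)
    )
    counter = 0
    for di in range(config.n_dendrites):
        length = float(
            rng.normal(config.dendrite_length_mean_um, config.dendrite_length_sd_um)
        )
        length = max(length, config.cluster_scale_um + 1.0)  # keep geometry feasible
        d_id = f"d{di:03d}"
        dendrites.append(
            Dendrite(d_id, length, animal_id=config.animal_id, group=config.group)
        )
        # live spines as (position, volume, presence-so-far list)
        n0 = rng.poisson(config.baseline_density_per_um * length)
        live: list[dict] = []
        for _ in range(n0):
            live.append(
                {
                    "pos": float(rng.uniform(0, length)),
                    "vol": float(rng.lognormal(config.volume_logmean, config.volume_logsd)),
                    "present": [True],
                }
            )
        dead: list[dict] = []
        for _s in range(1, k):
            n_prev = len(live)
            survivors = []
            for sp in live:
                p_die = config.p_eliminate
                if config.elimination_volume_coeff != 0.0:
                    z = logit_elim + config.elimination_volume_coeff * (
                        config.volume_logmean - math.log(max(sp["vol"], eps))
                    )
                    p_die = 1.0 / (1.0 + math.exp(-z))
                if rng.random() < p_die:
                    sp["present"].append(False)
                    dead.append(sp)
                else:
                    sp["present"].append(True)
                    survivors.append(sp)
            live = survivors
            n_new = int(rng.binomial(n_prev, config.p_generate)) if n_prev else 0
            interval_new: list[float] = []
            for _ in range(n_new):
                if interval_new and rng.random() < config.cluster_bias:
                    anchor = interval_new[int(rng.integers(len(interval_new)))]
                    lo = max(0.0, anchor - config.cluster_scale_um)
                    hi = min(length, anchor + config.cluster_scale_um)
                    pos = float(rng.uniform(lo, hi))
                else:
                    pos = float(rng.uniform(0, length))
                interval_new.append(pos)
                live.append(
                    {
                        "pos": pos,
                        "vol": float(
                            rng.lognormal(config.volume_logmean, config.volume_logsd)
                        ),
                        "present": [False] * _s + [True],
                    }
                )
        for sp in live + dead:
            pres = sp["present"] + [False] * (k - len(sp["present"]))
            spines.append(
                SpineRecord(
                    spine_id=f"s{counter:05d}",
                    dendrite_id=d_id,
                    position_um=sp["pos"],
                    present=tuple(pres),
                    volume_norm=sp["vol"],
                )
            )
            counter += 1
    return SpineDataset(dendrites, spines)


# ---------------------------------------------------------------------------
# Axons


@dataclass(frozen=True)
class AxonSimConfig:
    """Parameters of the axon / intensity-profile generator."""

    n_axons_per_projection: int = 10
    axon_length_um: float = 60.0
    bouton_density_per_um: dict = field(
        default_factory=lambda: {"ipsilateral": 0.12, "contralateral": 0.08}
    )
    p_generate: float = 0.15
    p_eliminate: float = 0.15
    amplitude_ratio_range: tuple[float, float] = (2.2, 3.5)
    decoy_density_per_um: float = 0.02
    decoy_ratio_range: tuple[float, float] = (1.2, 1.8)
    min_spacing_um: float = 2.0   # varicosities closer than this are not resolvable
    bump_sigma_um: float = 0.5
    sample_spacing_um: float = 0.1
    noise_sd: float = 0.05
    n_sessions: int = 3
    group: str = "UE"
    animal_id: str = "sim"
    seed: int = 0

    def validated(self) -> "AxonSimConfig":
        for name in ("p_generate", "p_eliminate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.axon_length_um <= 0:
            raise ValueError("axon_length_um must be positive")
        if self.amplitude_ratio_range[0] < 2.0:
            raise ValueError("true-bouton amplitude ratios must be >= 2")
        if self.decoy_ratio_range[1] >= 2.0:
            raise ValueError("decoy amplitude ratios must be < 2")
        return self


def generate_axon_profiles(config: AxonSimConfig):
    """Simulate axons, their bouton ground truth, and per-session profiles.

    Returns ``(AxonDataset, profiles)`` where ``profiles`` maps
    ``(axon_id, session_index)`` to ``(positions_um, intensity)`` arrays.
    The AxonDataset holds the ground-truth bouton records (position,
    per-session presence, true amplitude ratio); decoy bumps are present in
    the profiles but not in the ground truth.
    """
    config = config.validated()
    rng = _child(config.seed, 1)
    axons: list[Axon] = []
    boutons = []
    profiles: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    L = config.axon_length_um
    x = np.arange(0.0, L + config.sample_spacing_um / 2, config.sample_spacing_um)
    k = config.n_sessions
    counter = 0
    for proj in ("ipsilateral", "contralateral"):
        dens = config.bouton_density_per_um[proj]
        for ai in range(config.n_axons_per_projection):
            a_id = f"a_{proj[:4]}_{ai:03d}"
            axons.append(
                Axon(a_id, L, animal_id=config.animal_id, group=config.group, projection=proj)
            )
            def draw_position(existing: list[float]) -> float:
                # rejection sampling keeps bumps resolvable as separate peaks
                for _ in range(200):
                    pos = float(rng.uniform(0, L))
                    if all(abs(pos - e) >= config.min_spacing_um for e in existing):
                        return pos
                return float(rng.uniform(0, L))

            n0 = rng.poisson(dens * L)
            recs: list[dict] = []
            for _ in range(n0):
                recs.append(
                    {
                        "pos": draw_position([r["pos"] for r in recs]),
                        "ratio": float(rng.uniform(*config.amplitude_ratio_range)),
                        "present": [True],
                    }
                )
            for _s in range(1, k):
                n_prev = sum(r["present"][-1] for r in recs)
                for r in recs:
                    if r["present"][-1]:
                        r["present"].append(rng.random() >= config.p_eliminate)
                    else:
                        r["present"].append(False)
                n_new = int(rng.binomial(n_prev, config.p_generate)) if n_prev else 0
                for _ in range(n_new):
                    recs.append(
                        {
                            "pos": draw_position([r["pos"] for r in recs]),
                            "ratio": float(rng.uniform(*config.amplitude_ratio_range)),
                            "present": [False] * _s + [True],
                        }
                    )
            n_decoy = rng.poisson(config.decoy_density_per_um * L)
            decoys = []
            for _ in range(n_decoy):
                decoys.append(
                    (
                        draw_position([r["pos"] for r in recs] + [p for p, _ in decoys]),
                        float(rng.uniform(*config.decoy_ratio_range)),
                    )
                )
            for s in range(k):
                y = np.ones_like(x)
                for r in recs:
                    pres = r["present"] + [False] * (k - len(r["present"]))
                    if pres[s]:
                        y += (r["ratio"] - 1.0) * np.exp(
                            -0.5 * ((x - r["pos"]) / config.bump_sigma_um) ** 2
                        )
                for pos, ratio in decoys:
                    y += (ratio - 1.0) * np.exp(
                        -0.5 * ((x - pos) / config.bump_sigma_um) ** 2
                    )
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=x.shape)
                profiles[(a_id, s)] = (x.copy(), y)
            from .core_io import BoutonRecord

            for r in recs:
                pres = tuple(r["present"] + [False] * (k - len(r["present"])))
                boutons.append(
                    BoutonRecord(
                        bouton_id=f"b{counter:05d}",
                        axon_id=a_id,
                        position_um=r["pos"],
                        present=pres,
                        size_ratio=r["ratio"],
                    )
                )
                counter += 1
    return AxonDataset(axons, boutons), profiles


# ---------------------------------------------------------------------------
# z-stacks


def generate_zstack(
    blobs,
    *,
    shaft_amplitude: float = 1.0,
    shaft_axis_yx: tuple[float, float] | None = None,
    shaft_radius_um: float = 0.5,
    shape: tuple[int, int, int] = (51, 64, 64),
    voxel_um: tuple[float, float, float] = (0.5, 0.2, 0.2),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Build a small fluorescence z-stack from Gaussian blobs over a shaft.

    ``blobs`` is a list of ``(center_zyx_um, amplitude, sigma_um)``; the
    shaft is a cylinder of ``shaft_amplitude`` running along x at
    ``shaft_axis_yx`` (µm, defaults to the stack centre).  Deterministic for
    a fixed seed.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel_um
    z = np.arange(nz)[:, None, None] * dz
    yy = np.arange(ny)[None, :, None] * dy
    xx = np.arange(nx)[None, None, :] * dx
    stack = np.zeros(shape, dtype=float)
    if shaft_amplitude:
        if shaft_axis_yx is None:
            shaft_axis_yx = ((nz // 2) * dz, (ny // 2) * dy)
        z0, y0 = shaft_axis_yx
        r2 = (z - z0) ** 2 + (yy - y0) ** 2
        stack += shaft_amplitude * np.exp(-0.5 * r2 / shaft_radius_um**2)
    for center, amplitude, sigma in blobs:
        cz, cy, cx = center
        if not (0 <= cz <= (nz - 1) * dz and 0 <= cy <= (ny - 1) * dy and 0 <= cx <= (nx - 1) * dx):
            raise ValueError(f"blob centre {center} outside the stack")
        r2 = (z - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        stack += amplitude * np.exp(-0.5 * r2 / sigma**2)
    if noise_sd > 0:
        stack = stack + _child(seed, 2).normal(0.0, noise_sd, size=shape)
    return stack


def save_zstack(path, stack: np.ndarray) -> None:
    """Write a z-stack as a multi-page TIFF (one page per plane)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def load_zstack(path) -> np.ndarray:
    """Read a multi-page TIFF z-stack back into a (z, y, x) float array."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


# ---------------------------------------------------------------------------
# Paired logFC tables


@dataclass(frozen=True)
class ConcordanceSimConfig:
    """Parameters of the paired differential-expression generator."""

    n_modules: int = 10
    genes_per_module: int = 40
    rho: float = 0.5                    # target correlation of paired logFC
    concordant_fraction: float = 0.75   # expected per-module sign agreement
    significant_fraction: float = 0.8   # fraction with p_adj below 0.1
    logfc_sd: float = 0.5
    seed: int = 0

    def validated(self) -> "ConcordanceSimConfig":
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho outside [-1, 1]")
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise ValueError("concordant_fraction outside [0, 1]")
        return self


def generate_logfc_tables(config: ConcordanceSimConfig):
    """Emit paired model/human differential-expression tables plus a module map.

    Returns ``(model_df, human_df, module_map_df)`` with columns
    ``{gene_id, logfc, p_adj}`` and ``{gene_id, module_id}``.  Pairs are
    bivariate normal with correlation ``rho``; the human logFC sign is then
    re-drawn per gene so the expected sign agreement equals
    ``concordant_fraction`` exactly.
    """
    config = config.validated()
    rng = _child(config.seed, 3)
    rows_m, rows_h, rows_map = [], [], []
    sqrt1m = math.sqrt(1 - config.rho**2)
    for mi in range(config.n_modules):
        module_id = f"M{mi + 1:02d}"
        for gi in range(config.genes_per_module):
            gene = f"g_{module_id}_{gi:04d}"
            concordant = rng.random() < config.concordant_fraction
            # rejection-sample a bivariate-normal pair conditioned on the
            # assigned sign pattern; when concordant_fraction equals the
            # natural value 1/2 + arcsin(rho)/pi the mixture is exactly
            # bivariate normal and the sample correlation recovers rho
            for _ in range(1000):
                a = rng.normal(0.0, config.logfc_sd)
                b = config.rho * a + sqrt1m * rng.normal(0.0, config.logfc_sd)
                if a != 0.0 and b != 0.0 and (a * b > 0) == concordant:
                    break
            sig = rng.random() < config.significant_fraction
            p_m = rng.uniform(0, 0.1) if sig else rng.uniform(0.1, 1.0)
            p_h = rng.uniform(0, 0.1) if sig else rng.uniform(0.1, 1.0)
            rows_m.append({"gene_id": gene, "logfc": a, "p_adj": p_m})
            rows_h.append({"gene_id": gene, "logfc": b, "p_adj": p_h})
            rows_map.append({"gene_id": gene, "module_id": module_id})
    return pd.DataFrame(rows_m), pd.DataFrame(rows_h), pd.DataFrame(rows_map)
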
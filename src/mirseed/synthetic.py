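"""Synthetic cohort generator for plasma miRNA biomarker studies.

Emulates the statistical structure of a rat lateral fluid-percussion injury
(LFPI) biomarker cohort: three experimental arms (naive, sham-operated, TBI),
negative-binomial plasma small-RNA counts with variable library depth,
brain-enriched "injury-responsive" miRNAs whose plasma level scales with a
latent injury-severity variable that also drives lesion volume, epilepsy
outcomes that by default are *decoupled* from miRNA levels (the null
structure reported for post-traumatic epileptogenesis), hemolysis A414
absorbances, Poisson-partitioned ddPCR droplet readouts, and quantitative T2
voxel grids with a contiguous lesion core.

Every random quantity is derived deterministically from a single seed, so a
cohort reproduces bit-identically under a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Cohort",
    "T2Volume",
    "simulate_cohort",
    "simulate_droplet_readout",
    "simulate_t2_volume",
]

# ddPCR partition geometry of a standard 20 uL droplet reaction
DEFAULT_N_DROPLETS = 20_000
DEFAULT_DROPLET_VOLUME_UL = 0.00085

#: assays quantified by ddPCR in the validation arm: seven brain-enriched
#: targets plus the endogenous reference (most stable by geNorm)
DDPCR_TARGET_ASSAYS = (
    "miR-434-3p",
    "miR-9a-3p",
    "miR-136-3p",
    "miR-323-3p",
    "miR-124-3p",
    "miR-212-3p",
    "miR-132-3p",
)
DDPCR_REFERENCE_ASSAY = "miR-28-3p"

T2_TIMEPOINTS = ("D2", "D7", "D21")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated cohort.

    Defaults reproduce the design of the validation arm: 8 naive, 17
    sham-operated and 90 TBI animals, of which ~21 develop post-traumatic
    epilepsy, with plasma sampled on day 2 (D2) post-injury.

    Parameters
    ----------
    n_naive, n_sham, n_tbi
        Animals per experimental arm.
    epilepsy_rate
        Baseline probability that a TBI animal develops epilepsy (TBI+).
    n_mirna
        Number of distinct miRNAs in the count matrix.
    n_injury_responsive
        Number of brain-enriched miRNAs whose plasma abundance responds to
        injury; always the first ``n_injury_responsive`` miRNA ids.
    injury_log2fc
        Per-responsive-miRNA log2 effect of TBI over sham at mean severity.
        Scalar broadcasts; an array must have length ``n_injury_responsive``.
    sham_log2fc
        log2 effect of craniotomy (sham and TBI arms over naive) for
        responsive miRNAs.
    nb_dispersion
        NB dispersion alpha (variance = mu + alpha mu^2) of the counts.
    lib_size_mean, lib_size_cv
        Log-normal library-size distribution (mean and coefficient of
        variation of total mapped reads per sample).
    low_depth_factor
        Multiplier applied to the library size of the ``low_depth_group``
        arm, emulating the depth drop seen in sham libraries at the later
        timepoint (sham depth ~17% of TBI).
    low_depth_group
        Arm receiving the depth drop, or None to disable.
    lesion_coupling
        Slope linking latent severity to cortical lesion volume (mm^3 per
        unit severity); 0 removes the lesion/biomarker correlation.
    epilepsy_coupling
        Slope linking latent severity to the log-odds of epilepsy; the
        default 0 reproduces the reported null (miRNA levels carry no
        information about epileptogenesis).
    severity_sigma
        Log-scale SD of the latent injury severity (log-normal, mean 1).
    a414_mean, a414_sd
        Hemolysis absorbance distribution; with ``volume_ok_rate`` chosen so
        ~77% of samples pass QC (A414 < 0.25 and sufficient plasma).
    t2_grid
        Voxel grid dimensions of simulated quantitative T2 maps.
    t2_voxel_volume_mm3
        Volume of one T2 voxel.
    t2_normal_mean_ms, t2_normal_sd_ms
        Normal cortical T2 distribution; the defaults put the 2.5th/97.5th
        percentiles at ~45 and ~55 ms.
    seed
        Single global seed; all sub-streams derive from it.
    """

    n_naive: int = 8
    n_sham: int = 17
    n_tbi: int = 90
    epilepsy_rate: float = 21 / 90
    n_mirna: int = 300
    n_injury_responsive: int = 30
    injury_log2fc: float | tuple = 2.0
    sham_log2fc: float | tuple = 1.0
    nb_dispersion: float = 0.2
    lib_size_mean: float = 1.0e6
    lib_size_cv: float = 0.3
    low_depth_factor: float = 1.0
    low_depth_group: str | None = "sham"
    lesion_coupling: float = 30.0
    epilepsy_coupling: float = 0.0
    severity_sigma: float = 0.5
    a414_mean: float = 0.14
    a414_sd: float = 0.05
    volume_ok_rate: float = 0.78
    t2_grid: tuple = (16, 16, 8)
    t2_voxel_volume_mm3: float = 0.06
    t2_normal_mean_ms: float = 50.0
    t2_normal_sd_ms: float = 2.551
    t2_lesion_shift_ms: float = 30.0
    timepoint: str = "D2"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_naive", "n_sham", "n_tbi", "n_mirna", "n_injury_responsive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.epilepsy_rate <= 1.0:
            raise ValueError("epilepsy_rate must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.lib_size_mean <= 0 or self.lib_size_cv <= 0:
            raise ValueError("library size parameters must be positive")
        if self.n_injury_responsive > self.n_mirna:
            raise ValueError("n_injury_responsive cannot exceed n_mirna")
        if self.low_depth_factor <= 0:
            raise ValueError("low_depth_factor must be positive")


@dataclass
class T2Volume:
    """Quantitative T2 map: voxel grid of T2 values (ms) with a cortical mask."""

    data: np.ndarray          # T2 in ms
    voxel_volume_mm3: float
    mask: np.ndarray          # boolean, same shape
    sample_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.size == 0:
            raise ValueError("empty T2 grid")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match grid shape")
        if np.any(self.data <= 0):
            raise ValueError("T2 values must be positive")

    def to_voxel_table(self) -> pd.DataFrame:
        """Long-format voxel table (x, y, z, t2_ms, in_mask)."""
        idx = np.indices(self.data.shape).reshape(self.data.ndim, -1)
        return pd.DataFrame({
            "x": idx[0], "y": idx[1], "z": idx[2] if self.data.ndim > 2 else 0,
            "t2_ms": self.data.ravel(),
            "in_mask": self.mask.ravel().astype(int),
        })


@dataclass
class Cohort:
    """A simulated cohort with ground truth.

    ``counts`` is a miRNA x sample integer DataFrame; ``meta`` is indexed by
    sample id; ``ddpcr`` is a long table of droplet counts per sample/assay;
    ``t2`` maps (sample_id, timepoint) to a T2Volume for sham and TBI
    animals; ``truth`` records the latent severity, the injury-responsive
    miRNA set and the epilepsy labels actually drawn.
    """

    config: SimConfig
    counts: pd.DataFrame
    meta: pd.DataFrame
    ddpcr: pd.DataFrame
    t2: dict
    lesion_volume_mm3: pd.Series
    lesion_area_d182_mm2: pd.Series
    truth: dict

    def write(self, outdir: str | Path) -> dict:
        """Write cohort tables as TSV/JSON under *outdir*; return a path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["counts"] = str(outdir / "counts.tsv")
        self.counts.to_csv(paths["counts"], sep="\t")
        paths["meta"] = str(outdir / "meta.tsv")
        self.meta.to_csv(paths["meta"], sep="\t")
        paths["ddpcr"] = str(outdir / "ddpcr.tsv")
        self.ddpcr.to_csv(paths["ddpcr"], sep="\t", index=False)
        lesions = pd.DataFrame({
            "lesion_volume_mm3": self.lesion_volume_mm3,
            "lesion_area_d182_mm2": self.lesion_area_d182_mm2,
        })
        paths["lesions"] = str(outdir / "lesions.tsv")
        lesions.to_csv(paths["lesions"], sep="\t")
        t2dir = outdir / "t2"
        t2dir.mkdir(exist_ok=True)
        for (sid, tp), vol in self.t2.items():
            p = t2dir / f"{sid}_{tp}.tsv"
            vol.to_voxel_table().to_csv(p, sep="\t", index=False)
        paths["t2_dir"] = str(t2dir)
        truth = dict(self.truth)
        truth["severity"] = {k: float(v) for k, v in truth["severity"].items()}
        paths["truth"] = str(outdir / "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, default=list)
        return paths


def _as_effect_vector(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or length {n}")
    return arr


def simulate_droplet_readout(
    true_concentration: float,
    n_droplets: int = DEFAULT_N_DROPLETS,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int]:
    """Simulate a ddPCR droplet readout.

    Each droplet is positive independently with probability
    ``1 - exp(-c * v)`` where *c* is the true concentration (copies/uL) and
    *v* the droplet volume (uL). Returns ``(positives, total)``.
    """
    if true_concentration < 0:
        raise ValueError("true_concentration must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be > 0")
    rng = np.random.default_rng(rng)
    p = 1.0 - np.exp(-true_concentration * droplet_volume)
    return int(rng.binomial(n_droplets, p)), int(n_droplets)


def simulate_t2_volume(
    grid_dims: tuple,
    lesion_fraction: float,
    normal_mean_ms: float = 50.0,
    normal_sd_ms: float = 2.551,
    lesion_shift_ms: float = 30.0,
    voxel_volume_mm3: float = 0.06,
    seed: np.random.Generator | int | None = None,
    sample_id: str = "",
    timepoint: str = "",
) -> T2Volume:
    """Simulate a quantitative T2 voxel grid with a contiguous lesion core.

    The lesion core is the ball (in grid distance) around the grid centre
    containing ~``lesion_fraction`` of the voxels; its T2 values are shifted
    by ``lesion_shift_ms``. Remaining voxels are Normal(mean, sd), floored
    at 1 ms to keep relaxation times physical.
    """
    if not 0.0 <= lesion_fraction <= 1.0:
        raise ValueError("lesion_fraction must lie in [0, 1]")
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) == 0 or np.prod(grid_dims) == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    data = rng.normal(normal_mean_ms, normal_sd_ms, size=grid_dims)
    n_vox = data.size
    n_lesion = int(round(lesion_fraction * n_vox))
    if n_lesion > 0:
        centre = [(d - 1) / 2.0 for d in grid_dims]
        idx = np.indices(grid_dims, dtype=float)
        # anisotropic distance so the "ball" respects the grid aspect ratio
        dist = np.sqrt(sum(((idx[k] - centre[k]) / max(grid_dims[k], 1)) ** 2
                           for k in range(len(grid_dims))))
        order = np.argsort(dist.ravel(), kind="stable")
        core = np.zeros(n_vox, dtype=bool)
        core[order[:n_lesion]] = True
        core = core.reshape(grid_dims)
        data[core] += lesion_shift_ms
    data = np.maximum(data, 1.0)
    return T2Volume(
        data=data,
        voxel_volume_mm3=voxel_volume_mm3,
        mask=np.ones(grid_dims, dtype=bool),
        sample_id=sample_id,
        timepoint=timepoint,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort under *config*.

    Counts are NB with mean ``lib_size x baseline_proportion x 2^(group
    log2fc + severity effect)`` and dispersion ``nb_dispersion``; latent
    severity is log-normal with mean 1 across TBI animals; lesion volume is
    ``lesion_coupling x severity`` (strictly monotone in severity); epilepsy
    labels are Bernoulli with log-odds ``logit(epilepsy_rate) +
    epilepsy_coupling x (severity - 1)``.
    """
    cfg = config
    root = np.random.default_rng(cfg.seed)
    # independent sub-streams, all derived from the single global seed
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("design", "counts", "severity", "ddpcr", "t2", "qc"),
        root.spawn(6) if hasattr(root, "spawn") else
        [np.random.default_rng(root.integers(2**31)) for _ in range(6)],
    )}

    groups = (["naive"] * cfg.n_naive + ["sham"] * cfg.n_sham + ["TBI"] * cfg.n_tbi)
    n_samples = len(groups)
    sample_ids = []
    counters: dict[str, int] = {}
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        sample_ids.append(f"{g}_{counters[g]:03d}")
    mirna_ids = [f"rno-miR-{i + 1:04d}" for i in range(cfg.n_mirna)]
    responsive = mirna_ids[: cfg.n_injury_responsive]

    injury_fx = _as_effect_vector(cfg.injury_log2fc, cfg.n_injury_responsive,
                                  "injury_log2fc")
    sham_fx = _as_effect_vector(cfg.sham_log2fc, cfg.n_injury_responsive,
                                "sham_log2fc")

    rng_d = streams["design"]
    rng_sev = streams["severity"]
    is_tbi = np.array([g == "TBI" for g in groups])
    is_sham = np.array([g == "sham" for g in groups])

    # latent severity: log-normal with mean 1 for TBI, 0 elsewhere
    sev = np.zeros(n_samples)
    sigma = cfg.severity_sigma
    sev[is_tbi] = rng_sev.lognormal(-0.5 * sigma**2, sigma, size=is_tbi.sum())

    # epilepsy labels (TBI only)
    eps = np.full(n_samples, np.nan)
    if cfg.n_tbi:
        if cfg.epilepsy_rate in (0.0, 1.0):
            p_epi = np.full(is_tbi.sum(), cfg.epilepsy_rate)
        else:
            logit0 = np.log(cfg.epilepsy_rate / (1 - cfg.epilepsy_rate))
            eta = logit0 + cfg.epilepsy_coupling * (sev[is_tbi] - 1.0)
            p_epi = 1.0 / (1.0 + np.exp(-eta))
        eps[is_tbi] = rng_d.binomial(1, p_epi)

    # seizure phenotype: only epileptic animals seize; clusters need >=3 seizures
    n_seiz = np.where(eps == 1, 1 + rng_d.poisson(3.0, size=n_samples), 0)
    n_seiz = np.where(np.isnan(eps), np.nan, n_seiz)
    clusters = (n_seiz >= 3) & (rng_d.random(n_samples) < 0.55)
    clusters = np.where(np.isnan(eps), np.nan, clusters.astype(float))

    # hemolysis + plasma volume QC variables
    rng_qc = streams["qc"]
    a414 = np.clip(rng_qc.normal(cfg.a414_mean, cfg.a414_sd, n_samples), 0.01, None)
    vol_ok = rng_qc.random(n_samples) < cfg.volume_ok_rate

    # baseline abundance spectrum: heavy-tailed log-normal proportions
    rng_c = streams["counts"]
    log_ab = rng_c.normal(0.0, 2.0, cfg.n_mirna)
    baseline = np.exp(log_ab)
    baseline /= baseline.sum()

    # library sizes (log-normal, optional low-depth arm)
    cv = cfg.lib_size_cv
    sd_log = np.sqrt(np.log(1 + cv**2))
    lib = rng_c.lognormal(np.log(cfg.lib_size_mean) - 0.5 * sd_log**2, sd_log,
                          n_samples)
    if cfg.low_depth_group is not None and cfg.low_depth_factor != 1.0:
        in_arm = np.array([g == cfg.low_depth_group for g in groups])
        lib[in_arm] *= cfg.low_depth_factor

    # per-sample per-miRNA log2 effect
    log2_effect = np.zeros((cfg.n_mirna, n_samples))
    r = cfg.n_injury_responsive
    if r:
        log2_effect[:r, is_sham] = sham_fx[:, None]
        log2_effect[:r, is_tbi] = (sham_fx[:, None]
                                   + injury_fx[:, None] * sev[is_tbi][None, :])
    mu = baseline[:, None] * lib[None, :] * np.exp2(log2_effect)

    # gamma-Poisson mixture = NB with variance mu + alpha mu^2
    alpha = cfg.nb_dispersion
    lam = rng_c.gamma(1.0 / alpha, alpha * mu)
    counts = rng_c.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=mirna_ids, columns=sample_ids)

    meta = pd.DataFrame({
        "group": groups,
        "timepoint": cfg.timepoint,
        "a414": a414,
        "epilepsy": pd.array([None if np.isnan(e) else bool(e) for e in eps],
                             dtype="boolean"),
        "n_seizures": pd.array([None if np.isnan(s) else int(s) for s in n_seiz],
                               dtype="Int64"),
        "has_clusters": pd.array([None if np.isnan(c) else bool(c) for c in clusters],
                                 dtype="boolean"),
        "plasma_volume_ok": vol_ok,
    }, index=pd.Index(sample_ids, name="sample_id"))

    # ddPCR assays: targets follow the same group/severity effects
    rng_p = streams["ddpcr"]
    assay_rows = []
    target_base = dict(zip(DDPCR_TARGET_ASSAYS,
                           (5.0, 2.0, 4.0, 6.0, 3.0, 8.0, 10.0)))  # copies/uL
    mean_sham_fx = float(sham_fx.mean()) if r else 0.0
    mean_injury_fx = float(injury_fx.mean()) if r else 0.0
    for j, sid in enumerate(sample_ids):
        g2 = (mean_sham_fx if is_sham[j] else
              (mean_sham_fx + mean_injury_fx * sev[j]) if is_tbi[j] else 0.0)
        for assay, base in target_base.items():
            conc = base * 2.0**g2 * rng_p.lognormal(0.0, 0.15)
            pos, tot = simulate_droplet_readout(conc, rng=rng_p)
            assay_rows.append((sid, assay, pos, tot, DEFAULT_DROPLET_VOLUME_UL))
        ref_conc = 100.0 * rng_p.lognormal(0.0, 0.15)
        pos, tot = simulate_droplet_readout(ref_conc, rng=rng_p)
        assay_rows.append((sid, DDPCR_REFERENCE_ASSAY, pos, tot,
                           DEFAULT_DROPLET_VOLUME_UL))
    ddpcr = pd.DataFrame(assay_rows, columns=["sample_id", "assay_id", "positives",
                                              "total", "droplet_volume_ul"])

    # lesion metrics: strictly monotone in severity
    lesion_vol = pd.Series(cfg.lesion_coupling * sev, index=sample_ids,
                           name="lesion_volume_mm3")
    lesion_area = pd.Series(
        np.where(is_tbi, 0.4 * cfg.lesion_coupling * np.power(sev, 2 / 3), 0.0),
        index=sample_ids, name="lesion_area_d182_mm2")

    # T2 maps for sham (no lesion) and TBI animals, three imaging timepoints
    rng_t = streams["t2"]
    grid_vol = float(np.prod(cfg.t2_grid)) * cfg.t2_voxel_volume_mm3
    t2 = {}
    for j, sid in enumerate(sample_ids):
        if not (is_tbi[j] or is_sham[j]):
            continue
        frac = min(0.6, lesion_vol.iloc[j] / grid_vol) if is_tbi[j] else 0.0
        for tp in T2_TIMEPOINTS:
            t2[(sid, tp)] = simulate_t2_volume(
                cfg.t2_grid, frac, cfg.t2_normal_mean_ms, cfg.t2_normal_sd_ms,
                cfg.t2_lesion_shift_ms, cfg.t2_voxel_volume_mm3,
                seed=rng_t, sample_id=sid, timepoint=tp)

    truth = {
        "severity": dict(zip(sample_ids, sev)),
        "injury_responsive": list(responsive),
        "epilepsy": {s: bool(e) for s, e in zip(sample_ids, eps)
                     if not np.isnan(e)},
    }
    return Cohort(config=cfg, counts=counts_df, meta=meta, ddpcr=ddpcr, t2=t2,
                  lesion_volume_mm3=lesion_vol, lesion_area_d182_mm2=lesion_area,
                  truth=truth)
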
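"""Seeded synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the package is testable without any external
download: this module fabricates (a) circular/linear RNA-seq count matrices
with a case-specific global circRNA elevation, (b) qPCR Ct tables with known
group effects and clinical covariates tied to a target's circ/lin ratio,
(c) nested per-nucleus responses (gaussian and negative-binomial) for the
mixed-model machinery, and (d) multi-channel fluorescence fields with
nuclei, CUG-like foci and an optional MBNL1 channel, each with a full
ground-truth record.

Counts are negative-binomial with lognormal per-sample library-size factors
(the overdispersed structure bulk RNA-seq shows); lineage random effects
enter foci-count means as lognormal multipliers (the standard hierarchical
count construction); nuclei are placed by rejection sampling with a minimum
gap so that watershed outcomes are unambiguous.  A single integer seed
feeds a hierarchical seed-spawning scheme, so generators are deterministic
and mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import ExpressionMatrix

__all__ = [
    "SimCohortConfig",
    "QpcrTarget",
    "SimQpcrConfig",
    "SimImageConfig",
    "FieldOfView",
    "gen_count_matrices",
    "gen_ct_table",
    "gen_nested_counts",
    "gen_nested_gaussian",
    "gen_foci_images",
]


# --------------------------------------------------------------------------
# cohort count matrices
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SimCohortConfig:
    """Cohort of case/control RNA-seq samples with a circRNA burden effect.

    ``circ_burden_effect`` multiplies every circRNA's expected count in case
    samples (1.0 = null).  ``dispersion`` is the NB2 alpha (variance =
    mu + alpha * mu^2).  Library sizes are lognormal around ``libsize_mean``
    through per-sample size factors that hit circular and linear counts
    alike, as true sequencing depth does.
    """

    n_case: int = 10
    n_control: int = 10
    n_circ: int = 300
    n_genes: int = 2000
    libsize_mean: float = 1e6
    circ_burden_effect: float = 2.0
    dispersion: float = 0.3
    circ_mean_count: float = 20.0
    libsize_sd_log: float = 0.3
    feature_sd_log: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_circ", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.circ_burden_effect <= 0:
            raise ValueError("circ_burden_effect must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 sampling: shape r = 1/alpha, p = r / (r + mean)."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def gen_count_matrices(
    config: SimCohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Circular and linear count matrices plus the generating ground truth.

    Case samples have every circRNA mean scaled by ``circ_burden_effect``;
    linear genes are unaffected.  The recorded library size of each sample
    is its total linear (transcriptome-mapped) count, which is what CPM
    normalization downstream divides by.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_mu, rng_size, rng_circ, rng_lin = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n_case + config.n_control
    is_case = np.array([True] * config.n_case + [False] * config.n_control)
    samples = [f"S{i+1:03d}" for i in range(n)]
    groups = pd.Series(np.where(is_case, "DM1", "CTRL"), index=samples)

    gene_mu = rng_mu.lognormal(
        mean=np.log(config.libsize_mean / config.n_genes) - config.feature_sd_log**2 / 2,
        sigma=config.feature_sd_log,
        size=config.n_genes,
    )
    circ_mu = rng_mu.lognormal(
        mean=np.log(config.circ_mean_count) - config.feature_sd_log**2 / 2,
        sigma=config.feature_sd_log,
        size=config.n_circ,
    )
    size_factors = rng_size.lognormal(mean=0.0, sigma=config.libsize_sd_log, size=n)

    lin_mean = gene_mu[:, None] * size_factors[None, :]
    circ_scale = np.where(is_case, config.circ_burden_effect, 1.0)
    circ_mean = circ_mu[:, None] * size_factors[None, :] * circ_scale[None, :]

    lin_counts = _nb_draw(rng_lin, lin_mean, config.dispersion)
    circ_counts = _nb_draw(rng_circ, circ_mean, config.dispersion)

    lib = pd.Series(lin_counts.sum(axis=0).astype(float), index=samples)
    lin_df = pd.DataFrame(lin_counts, index=[f"gene{i}" for i in range(config.n_genes)], columns=samples)
    circ_df = pd.DataFrame(
        circ_counts,
        index=[f"chr1:{1000*i}-{1000*i+500}" for i in range(config.n_circ)],
        columns=samples,
    )
    circ_mat = ExpressionMatrix(circ_df, lib, groups, feature_class="circular")
    lin_mat = ExpressionMatrix(lin_df, lib, groups, feature_class="linear")
    truth = {
        "is_case": is_case,
        "size_factors": size_factors,
        "circ_means": circ_mu,
        "gene_means": gene_mu,
        "circ_burden_effect": config.circ_burden_effect,
    }
    return circ_mat, lin_mat, truth


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class QpcrTarget:
    """A gene with circular and linear amplicons and true log2 case effects."""

    name: str
    circ_effect: float = 0.0  # log2 case-vs-control on the circular amplicon
    lin_effect: float = 0.0
    circ_base_ct: float = 28.0
    lin_base_ct: float = 24.0


@dataclass(frozen=True)
class SimQpcrConfig:
    """qPCR cohort: Ct = base - true log2 expression + gaussian noise.

    A per-sample loading shift (same for every amplicon of a sample)
    emulates variable RNA input; reference normalization must cancel it.
    Biological sample-to-sample variability enters as a per-sample latent
    log2 expression around the group mean.  Clinical covariates (CTG repeat
    size, MRC megascore) are generated with the stated linear slopes against
    the first target's true per-sample circ/lin log2 ratio.
    """

    n_case: int = 24
    n_control: int = 16
    targets: tuple[QpcrTarget, ...] = (QpcrTarget("ARHGAP10", circ_effect=1.5, lin_effect=0.0),)
    ref_ct_mean: float = 20.0
    noise_sd: float = 0.2
    bio_sd: float = 0.5
    loading_sd: float = 0.5
    n_replicates: int = 3
    ctg_slope: float = 150.0
    mrc_slope: float = -8.0
    ctg_intercept: float = 400.0
    mrc_intercept: float = 45.0
    ctg_noise_sd: float = 80.0
    mrc_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.targets) == 0:
            raise ValueError("at least one qPCR target required")


def gen_ct_table(config: SimQpcrConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Long-format Ct table, clinical covariate table, and ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_bio, rng_tech, rng_clin = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_case + config.n_control
    is_case = np.array([True] * config.n_case + [False] * config.n_control)
    samples = [f"P{i+1:03d}" for i in range(n)]
    groups = np.where(is_case, "DM1", "CTRL")
    loading = rng_bio.normal(0.0, config.loading_sd, size=n)

    rows = []
    true_expr: dict[tuple[str, str], np.ndarray] = {}
    for t in config.targets:
        for cls, base, effect in (
            ("circular", t.circ_base_ct, t.circ_effect),
            ("linear", t.lin_base_ct, t.lin_effect),
        ):
            latent = effect * is_case + rng_bio.normal(0.0, config.bio_sd, size=n)
            true_expr[(t.name, cls)] = latent
            for i, s in enumerate(samples):
                for rep in range(config.n_replicates):
                    ct = base - latent[i] + loading[i] + rng_tech.normal(0.0, config.noise_sd)
                    rows.append(
                        {
                            "sample": s,
                            "group": groups[i],
                            "target": t.name,
                            "amplicon_class": cls,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    for ref in ("UBC", "RPL23"):
        for i, s in enumerate(samples):
            for rep in range(config.n_replicates):
                ct = config.ref_ct_mean + loading[i] + rng_tech.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "sample": s,
                        "group": groups[i],
                        "target": ref,
                        "amplicon_class": "reference",
                        "replicate": rep + 1,
                        "ct": ct,
                    }
                )
    ct_table = pd.DataFrame(rows)

    anchor = config.targets[0]
    true_ratio = (
        (anchor.lin_base_ct - anchor.circ_base_ct)
        + true_expr[(anchor.name, "circular")]
        - true_expr[(anchor.name, "linear")]
    )
    centred = true_ratio - true_ratio.mean()
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "ctg": config.ctg_intercept
            + config.ctg_slope * centred
            + rng_clin.normal(0.0, config.ctg_noise_sd, size=n),
            "mrc": config.mrc_intercept
            + config.mrc_slope * centred
            + rng_clin.normal(0.0, config.mrc_noise_sd, size=n),
        }
    )
    truth = {
        "is_case": is_case,
        "loading": loading,
        "true_expression": true_expr,
        "true_ratio_anchor": true_ratio,
        "anchor_target": anchor.name,
    }
    return ct_table, clinical, truth


# --------------------------------------------------------------------------
# nested responses (shared by image generator and the model simulations)
# --------------------------------------------------------------------------
def gen_nested_counts(
    state_means: dict[str, float],
    n_experiments: int = 4,
    n_samples_per_state: int = 3,
    n_nuclei_per_sample: int = 50,
    experiment_sd: float = 0.2,
    sample_sd: float = 0.2,
    dispersion: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-nucleus foci counts with lognormal lineage multipliers.

    Treatment state is a sample-level assignment (each sample/image receives
    one treatment, as in a transfection experiment): every experiment
    contributes ``n_samples_per_state`` samples per state.  The expected
    count of a nucleus is ``state_mean * exp(u_exp) * exp(u_sample)`` with
    gaussian ``u`` on the log scale; counts are NB2 unless
    ``dispersion == 0``, which makes them deterministic (``round(mean)``) —
    the exact-count limit used to build unambiguous imaging fixtures.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for e in range(n_experiments):
        u_exp = rng.normal(0.0, experiment_sd)
        for state, mean in state_means.items():
            for srep in range(n_samples_per_state):
                u_samp = rng.normal(0.0, sample_sd)
                mu = mean * np.exp(u_exp + u_samp)
                if dispersion == 0:
                    counts = np.full(n_nuclei_per_sample, int(round(mean)))
                else:
                    counts = _nb_draw(rng, np.full(n_nuclei_per_sample, mu), dispersion)
                for nuc, c in enumerate(counts):
                    rows.append(
                        {
                            "experiment": f"E{e+1}",
                            "sample": f"E{e+1}:{state}:S{srep+1}",
                            "state": state,
                            "nucleus": nuc + 1,
                            "foci_count": int(c),
                        }
                    )
    return pd.DataFrame(rows)


def gen_nested_gaussian(
    state_effects: dict[str, float],
    n_experiments: int = 4,
    n_samples_per_experiment: int = 3,
    n_nuclei_per_sample: int = 50,
    experiment_sd: float = 0.3,
    sample_sd: float = 0.2,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Continuous nested responses with additive random intercepts.

    States alternate across nuclei within each sample (a within-image
    contrast), so the state effect is estimated against the residual
    stratum while experiment and sample intercepts absorb batch noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    states = list(state_effects)
    rows = []
    for e in range(n_experiments):
        u_exp = rng.normal(0.0, experiment_sd)
        for s in range(n_samples_per_experiment):
            u_samp = rng.normal(0.0, sample_sd)
            for nuc in range(n_nuclei_per_sample):
                state = states[nuc % len(states)]
                value = (
                    state_effects[state]
                    + u_exp
                    + u_samp
                    + rng.normal(0.0, residual_sd)
                )
                rows.append(
                    {
                        "experiment": f"E{e+1}",
                        "sample": f"E{e+1}:S{s+1}",
                        "state": state,
                        "nucleus": nuc + 1,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fluorescence fields
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SimImageConfig:
    """Synthetic FISH field layout and per-state foci count distribution.

    ``foci_count_distribution`` maps treatment state to ``(mean,
    dispersion)`` of the per-nucleus NB count (dispersion 0 = exact counts).
    Nuclei are bright discs on the blue channel, placed by rejection
    sampling with at least ``min_gap`` px between discs and fully interior
    to the field; foci are smaller bright discs on the red channel with at
    least ``2*focus_radius + 3`` px between centres so segmentation is
    unambiguous.  ``mbnl1_fraction`` of foci are co-located on a green
    channel.  Random intercepts act as lognormal multipliers on the count
    mean at the experiment and sample levels.
    """

    width: int = 512
    height: int = 512
    n_experiments: int = 1
    n_samples_per_experiment: int = 1
    n_nuclei_per_image: int = 20
    foci_count_distribution: dict = field(
        default_factory=lambda: {"si-NTC": (3.0, 0.0)}
    )
    focus_radius: int = 2
    focus_intensity: float = 0.9
    background_level: float = 0.05
    nucleus_radius_range: tuple[int, int] = (12, 18)
    nucleus_intensity: float = 0.8
    nucleus_background: float = 0.02
    experiment_sd: float = 0.0
    sample_sd: float = 0.0
    noise_sd: float = 0.01
    mbnl1_fraction: float = 0.0
    min_gap: int = 2
    border_margin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focus_intensity <= self.background_level:
            raise ValueError("focus_intensity must exceed background_level")
        if self.focus_radius >= self.nucleus_radius_range[0]:
            raise ValueError("focus_radius must be smaller than the smallest nucleus radius")
        for name in ("n_experiments", "n_samples_per_experiment", "n_nuclei_per_image"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FieldOfView:
    """One simulated image: channels plus its lineage labels."""

    experiment: str
    sample: str
    state: str
    channels: dict[str, np.ndarray]  # "nuclei", "foci", optional "mbnl1"


def _disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_nuclei(rng, config) -> list[tuple[tuple[int, int], int]]:
    placed: list[tuple[tuple[int, int], int]] = []
    r_lo, r_hi = config.nucleus_radius_range
    tries = 0
    while len(placed) < config.n_nuclei_per_image and tries < 20000:
        tries += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        margin = r + config.border_margin
        cy = int(rng.integers(margin, config.height - margin))
        cx = int(rng.integers(margin, config.width - margin))
        ok = all(
            (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + config.min_gap) ** 2
            for (oy, ox), orad in placed
        )
        if ok:
            placed.append(((cy, cx), r))
    if len(placed) < config.n_nuclei_per_image:
        raise ValueError(
            "could not place the requested number of nuclei; "
            "reduce n_nuclei_per_image or nucleus radii"
        )
    return placed


def _place_foci(rng, center, nucleus_radius, n_foci, focus_radius) -> list[tuple[int, int]]:
    min_sep = 2 * focus_radius + 3
    max_r = nucleus_radius - focus_radius - 2
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n_foci and tries < 5000:
        tries += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = max_r * np.sqrt(rng.uniform())
        fy = int(round(center[0] + rad * np.sin(ang)))
        fx = int(round(center[1] + rad * np.cos(ang)))
        if (fy - center[0]) ** 2 + (fx - center[1]) ** 2 > max_r**2:
            continue
        if all((fy - oy) ** 2 + (fx - ox) ** 2 >= min_sep**2 for oy, ox in placed):
            placed.append((fy, fx))
    return placed  # may be fewer than requested if the nucleus is crowded


def gen_foci_images(config: SimImageConfig) -> tuple[list[FieldOfView], dict]:
    """Simulated fields and their ground truth.

    Returns ``(fields, truth)`` where ``truth`` carries two data frames:
    ``nuclei`` (lineage, nucleus id, centre, radius, true foci count) and
    ``foci`` (lineage, nucleus id, centre, area, mbnl1 flag).  Every focus
    centre lies inside its nucleus disc and per-nucleus counts equal the
    number of listed centres by construction.
    """
    ss = np.random.SeedSequence(config.seed)
    states = list(config.foci_count_distribution)
    n_images = config.n_experiments * config.n_samples_per_experiment * len(states)
    child_seeds = ss.spawn(n_images + 1)
    rng_global = np.random.default_rng(child_seeds[0])

    u_exp = {
        f"E{e+1}": rng_global.normal(0.0, config.experiment_sd)
        for e in range(config.n_experiments)
    }

    fields: list[FieldOfView] = []
    nuc_rows = []
    focus_rows = []
    img_idx = 1
    for e in range(config.n_experiments):
        exp_id = f"E{e+1}"
        for state in states:
            mean, disp = config.foci_count_distribution[state]
            for s in range(config.n_samples_per_experiment):
                sample_id = f"{exp_id}:{state}:S{s+1}"
                rng = np.random.default_rng(child_seeds[img_idx])
                img_idx += 1
                u_samp = rng.normal(0.0, config.sample_sd)
                mu = mean * np.exp(u_exp[exp_id] + u_samp)

                shape = (config.height, config.width)
                blue = np.full(shape, config.nucleus_background)
                red = np.full(shape, config.background_level)
                green = np.full(shape, config.background_level)

                nuclei = _place_nuclei(rng, config)
                for nuc_id, (center, radius) in enumerate(nuclei, start=1):
                    blue[_disc_mask(shape, center, radius)] = config.nucleus_intensity
                    if disp == 0:
                        n_foci = int(round(mean))
                    else:
                        n_foci = int(_nb_draw(rng, np.array([mu]), disp)[0])
                    centers = _place_foci(
                        rng, center, radius, n_foci, config.focus_radius
                    )
                    for fy, fx in centers:
                        fmask = _disc_mask(shape, (fy, fx), config.focus_radius)
                        red[fmask] = config.focus_intensity
                        is_mbnl1 = bool(rng.uniform() < config.mbnl1_fraction)
                        if is_mbnl1:
                            green[fmask] = config.focus_intensity
                        focus_rows.append(
                            {
                                "experiment": exp_id,
                                "sample": sample_id,
                                "state": state,
                                "nucleus": nuc_id,
                                "row": fy,
                                "col": fx,
                                "area": int(fmask.sum()),
                                "intensity": config.focus_intensity,
                                "mbnl1": is_mbnl1,
                            }
                        )
                    nuc_rows.append(
                        {
                            "experiment": exp_id,
                            "sample": sample_id,
                            "state": state,
                            "nucleus": nuc_id,
                            "row": center[0],
                            "col": center[1],
                            "radius": radius,
                            "foci_count": len(centers),
                        }
                    )

                if config.noise_sd > 0:
                    blue = blue + rng.normal(0.0, config.noise_sd, shape)
                    red = red + rng.normal(0.0, config.noise_sd, shape)
                    green = green + rng.normal(0.0, config.noise_sd, shape)
                channels = {
                    "nuclei": np.clip(blue, 0.0, 1.0),
                    "foci": np.clip(red, 0.0, 1.0),
                }
                if config.mbnl1_fraction > 0:
                    channels["mbnl1"] = np.clip(green, 0.0, 1.0)
                fields.append(
                    FieldOfView(
                        experiment=exp_id, sample=sample_id, state=state, channels=channels
                    )
                )

    truth = {
        "nuclei": pd.DataFrame(nuc_rows),
        "foci": pd.DataFrame(focus_rows),
    }
    return fields, truth
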
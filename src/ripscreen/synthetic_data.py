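"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: an IP /
mock-IP RIP-seq pair with a planted bound-transcript set, mutant vs
wild-type gonad RNA-seq (2 replicates each, negative-binomial counts) with
planted class-I (up in mutant, soma-biased) and class-II (down in mutant)
genes, a rescue-strain gonad sample set, a whole-animal sample mixing
gonad and soma profiles, and stained-worm images with analytically known
lipid indices.

Counts are NB with variance = mu + dispersion * mu**2. Because RPM is a
compositional measure, a bound set carrying weight share ``s`` of the
library can show at most a 1/s-fold RPM enrichment; the defaults
(fraction_bound 0.05, 16-fold planted IP enrichment, giving a realized
RPM-scale fold of ~9) keep the published FC >= 4 calling rule well inside
its operating range. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation, SampleMeta, ValidationError
from .oro_imaging import WormImage


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-truth simulation (defaults = the hard
    2-replicate design the pipeline is meant to survive)."""

    n_genes: int = 5000
    depth: int = 5_000_000
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    fraction_bound: float = 0.05
    fraction_class_i: float = 0.03
    fraction_class_ii: float = 0.005
    class_i_fold: float = 8.0
    class_ii_fold: float = 8.0
    ip_enrichment_fold: float = 16.0
    soma_fold: float = 8.0
    germline_attenuation: float = 0.1
    rescue_efficiency: float = 0.8
    replicates: int = 2
    soma_mix: float = 0.5
    length_min: int = 300
    length_max: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_bound", "fraction_class_i", "fraction_class_ii",
                     "rescue_efficiency", "soma_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_class_i + self.fraction_class_ii > self.fraction_bound:
            raise ValidationError(
                "class fractions exceed fraction_bound; planted classes must be bound"
            )
        # fold = 1 is allowed so a no-effect null run is expressible
        for name in ("class_i_fold", "class_ii_fold", "ip_enrichment_fold", "soma_fold"):
            if getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 < self.germline_attenuation <= 1:
            raise ValidationError("germline_attenuation must be in (0, 1]")


@dataclass
class PlantedTruth:
    bound: tuple[str, ...]
    class_i: tuple[str, ...]
    class_ii: tuple[str, ...]
    rescued: tuple[str, ...]
    true_means: pd.DataFrame  # relative expression per condition profile


@dataclass
class SyntheticBundle:
    rip: CountMatrix           # ip + mock_ip samples
    gonad: CountMatrix         # wild_type / mutant / rescue replicates
    whole_animal: CountMatrix
    annotation: GeneAnnotation
    truth: PlantedTruth
    config: SimulationConfig = field(repr=False, default=None)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Deterministic (seeded) synthetic bundle for all sequencing stages."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"gene_{i:05d}" for i in range(n)])
    w = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)

    n_bound = round(config.fraction_bound * n)
    n_c1 = round(config.fraction_class_i * n)
    n_c2 = round(config.fraction_class_ii * n)
    perm = rng.permutation(n)
    bound_idx = perm[:n_bound]
    c1_idx = perm[:n_c1]
    c2_idx = perm[n_c1:n_c1 + n_c2]
    n_rescued = round(config.rescue_efficiency * n_c1)
    rescued_idx = rng.choice(c1_idx, size=n_rescued, replace=False) if n_c1 else np.array([], int)

    # condition-specific relative expression profiles
    gonad_wt = w.copy()
    gonad_wt[c1_idx] *= config.germline_attenuation  # soma genes, low in germline
    gonad_mut = gonad_wt.copy()
    gonad_mut[c1_idx] *= config.class_i_fold
    gonad_mut[c2_idx] /= config.class_ii_fold
    gonad_res = gonad_mut.copy()
    gonad_res[rescued_idx] = gonad_wt[rescued_idx]
    soma = w.copy()
    soma[c1_idx] *= config.soma_fold
    whole = config.soma_mix * soma / soma.sum() + (1 - config.soma_mix) * gonad_wt / gonad_wt.sum()
    ip = w.copy()
    ip[bound_idx] *= config.ip_enrichment_fold
    mock = w.copy()

    profiles = {
        "ip": ip, "mock_ip": mock, "gonad_wild_type": gonad_wt,
        "gonad_mutant": gonad_mut, "gonad_rescue": gonad_res, "whole_animal": whole,
    }
    true_means = pd.DataFrame(
        {name: prof / prof.sum() for name, prof in profiles.items()}, index=genes
    )

    def draw(profile: np.ndarray) -> np.ndarray:
        mean = config.depth * profile / profile.sum()
        return _nb_draw(rng, mean, config.dispersion)

    rip_counts = pd.DataFrame(
        {"ip_rep1": draw(ip), "mock_rep1": draw(mock)}, index=genes
    )
    rip_meta = [
        SampleMeta("ip_rep1", "ip", "variant-E454Q", 15.0, 1),
        SampleMeta("mock_rep1", "mock_ip", "wild_type", 15.0, 1),
    ]

    gonad_cols, gonad_meta = {}, []
    for geno, prof in [("wild_type", gonad_wt), ("mutant", gonad_mut), ("rescue", gonad_res)]:
        for rep in range(1, config.replicates + 1):
            sid = f"gonad_{geno}_rep{rep}"
            gonad_cols[sid] = draw(prof)
            gonad_meta.append(SampleMeta(sid, "gonad", geno, 25.0, rep))
    gonad_counts = pd.DataFrame(gonad_cols, index=genes)

    whole_counts = pd.DataFrame({"whole_rep1": draw(whole)}, index=genes)
    whole_meta = [SampleMeta("whole_rep1", "whole_animal", "wild_type", 25.0, 1)]

    annotation = GeneAnnotation(
        pd.Series(
            rng.integers(config.length_min, config.length_max + 1, n),
            index=genes, name="length_nt",
        )
    )
    truth = PlantedTruth(
        bound=tuple(sorted(genes[bound_idx])),
        class_i=tuple(sorted(genes[c1_idx])),
        class_ii=tuple(sorted(genes[c2_idx])),
        rescued=tuple(sorted(genes[rescued_idx])),
        true_means=true_means,
    )
    return SyntheticBundle(
        rip=CountMatrix(rip_counts, rip_meta),
        gonad=CountMatrix(gonad_counts, gonad_meta),
        whole_animal=CountMatrix(whole_counts, whole_meta),
        annotation=annotation,
        truth=truth,
        config=config,
    )


def simulate_binding_conditions(
    config: SimulationConfig,
    condition_folds: dict[str, float],
) -> dict[str, CountMatrix]:
    """IP/mock count pairs for several variant/temperature conditions whose
    planted enrichment folds differ (for binding-strength ranking)."""
    out = {}
    for i, (label, fold) in enumerate(condition_folds.items()):
        if fold <= 1:
            raise ValidationError(f"condition {label!r} needs fold > 1")
        cfg = replace(config, ip_enrichment_fold=fold, seed=config.seed + 1000 + i)
        out[label] = simulate_bundle(cfg).rip
    return out


# ---------------------------------------------------------------------------
# Oil Red O image simulation


def simulate_worm_image(
    rng: np.random.Generator,
    amplitude: float = 0.3,
    n_blobs: int = 5,
    blob_radius: int = 6,
    shape: tuple[int, int] = (120, 200),
    worm_gray: float = 0.5,
    background: float = 0.95,
    noise_sd: float = 0.005,
) -> tuple[WormImage, float]:
    """One stained-worm image: dark ellipse on a light background with
    circular stain blobs of uniform red excess.

    Returns the image and its analytic lipid index — the clean (noise-free)
    stain excess summed over the worm, divided by worm area, which accounts
    exactly for blob overlap.
    """
    h, w = shape
    cy, cx, ry, rx = h / 2, w / 2, h / 3, w / 2.5
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    worm_area = int(mask.sum())
    if n_blobs * np.pi * blob_radius ** 2 > worm_area:
        raise ValidationError("total blob area exceeds the worm area")
    excess = np.zeros(shape)
    for _ in range(n_blobs):
        while True:
            by = cy + (rng.uniform(-1, 1)) * ry * 0.7
            bx = cx + (rng.uniform(-1, 1)) * rx * 0.7
            if ((by - cy) / ry) ** 2 + ((bx - cx) / rx) ** 2 <= 0.7 ** 2:
                break
        blob = (yy - by) ** 2 + (xx - bx) ** 2 <= blob_radius ** 2
        excess[blob & mask] = amplitude
    true_index = float(excess[mask].sum()) / worm_area

    pixels = np.full((h, w, 3), background)
    for c in range(3):
        pixels[:, :, c][mask] = worm_gray
    pixels[:, :, 0] += excess
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    return WormImage(pixels, mask), true_index


def simulate_oro_cohort(
    group_effects: dict[str, float],
    n_per_group: int = 30,
    base_amplitude: float = 0.2,
    worm_cv: float = 0.15,
    seed: int = 0,
    **image_kwargs,
) -> tuple[list[WormImage], list[str], list[float]]:
    """Cohort of worm images with per-group mean stain effects and
    log-normal worm-to-worm variability; returns (images, group labels,
    analytic lipid indices)."""
    rng = np.random.default_rng(seed)
    images, labels, truths = [], [], []
    for group, effect in group_effects.items():
        mean_amp = base_amplitude * effect
        for _ in range(n_per_group):
            amp = mean_amp * np.exp(rng.normal(0, worm_cv) - worm_cv ** 2 / 2)
            amp = min(amp, 0.45)  # stay clear of channel saturation
            img, truth = simulate_worm_image(rng, amplitude=amp, **image_kwargs)
            images.append(img)
            labels.append(group)
            truths.append(truth)
    return images, labels, truths


# ---------------------------------------------------------------------------
# recovery metrics


def _set_metrics(true_set: set, called_set: set) -> tuple[float, float, float]:
    tp = len(true_set & called_set)
    sens = tp / len(true_set) if true_set else np.nan
    prec = tp / len(called_set) if called_set else np.nan
    f1 = (
        2 * sens * prec / (sens + prec)
        if called_set and true_set and (sens + prec) > 0
        else np.nan
    )
    return sens, prec, f1


def evaluate_recovery(
    truth: PlantedTruth,
    bound_called,
    class_i_called,
    class_ii_called,
    sef_table: pd.DataFrame | None = None,
    fraction_rescued: float | None = None,
    rescue_efficiency: float | None = None,
) -> pd.DataFrame:
    """Sensitivity / precision / F1 of the called sets against the planted
    truth, plus the SEF rank-AUC (class I vs background) and the rescue
    fraction error when the inputs are given."""
    universe = set(truth.true_means.index)
    rows = []
    for name, true_set, called in [
        ("bound", set(truth.bound), set(bound_called)),
        ("class_i", set(truth.class_i), set(class_i_called)),
        ("class_ii", set(truth.class_ii), set(class_ii_called)),
    ]:
        if not called <= universe:
            raise ValidationError(f"called {name} set contains ids outside the bundle")
        sens, prec, f1 = _set_metrics(true_set, called)
        rows.append((name, "sensitivity", sens))
        rows.append((name, "precision", prec))
        rows.append((name, "f1", f1))
    if sef_table is not None:
        from scipy.stats import mannwhitneyu

        sef = sef_table.set_index("gene_id")["sef"]
        pos = sef.loc[sef.index.intersection(list(truth.class_i))].to_numpy()
        neg = sef.loc[sef.index.difference(list(truth.class_i))].to_numpy()
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        rows.append(("sef", "rank_auc", float(u) / (len(pos) * len(neg))))
    if fraction_rescued is not None:
        planted = (
            rescue_efficiency
            if rescue_efficiency is not None
            else len(truth.rescued) / max(len(truth.class_i), 1)
        )
        rows.append(("rescue", "fraction_rescued", fraction_rescued))
        rows.append(("rescue", "abs_error", abs(fraction_rescued - planted)))
    return pd.DataFrame(rows, columns=["target", "metric", "value"])


# ---------------------------------------------------------------------------
# on-disk bundle


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write the bundle as TSVs (+ truth lists and the config used)."""
    from . import io as rio
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cm in [("rip", bundle.rip), ("gonad", bundle.gonad),
                     ("whole_animal", bundle.whole_animal)]:
        paths[f"{name}_counts"] = outdir / f"{name}_counts.tsv"
        rio.write_count_matrix(cm, paths[f"{name}_counts"])
        paths[f"{name}_metadata"] = outdir / f"{name}_metadata.tsv"
        rio.write_sample_metadata(cm.samples, paths[f"{name}_metadata"])
    paths["annotation"] = outdir / "annotation.tsv"
    rio.write_gene_lengths(bundle.annotation, paths["annotation"])
    for name in ("bound", "class_i", "class_ii", "rescued"):
        paths[f"truth_{name}"] = outdir / f"truth_{name}.txt"
        rio.write_gene_list(getattr(bundle.truth, name), paths[f"truth_{name}"])
    paths["config"] = outdir / "simulation_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {k: (v if not isinstance(v, (np.integer, np.floating)) else v.item())
             for k, v in vars(bundle.config).items()},
            fh, sort_keys=True,
        )
    return paths


def read_bundle(indir) -> SyntheticBundle:
    """Load a bundle directory written by :func:`write_bundle` (truth lists
    and the simulation config are optional — real datasets lack them)."""
    from . import io as rio
    import yaml

    indir = Path(indir)
    cms = {}
    for name in ("rip", "gonad", "whole_animal"):
        cms[name] = rio.read_count_matrix(
            indir / f"{name}_counts.tsv", str(indir / f"{name}_metadata.tsv")
        )
    annotation = rio.read_gene_lengths(indir / "annotation.tsv", "tsv")
    truth = None
    if (indir / "truth_bound.txt").exists():
        sets = {
            name: tuple(rio.read_gene_list(indir / f"truth_{name}.txt"))
            for name in ("bound", "class_i", "class_ii", "rescued")
        }
        truth = PlantedTruth(
            **sets, true_means=pd.DataFrame(index=cms["rip"].counts.index)
        )
    config = None
    if (indir / "simulation_config.yaml").exists():
        with open(indir / "simulation_config.yaml") as fh:
            config = SimulationConfig(**yaml.safe_load(fh))
    return SyntheticBundle(
        rip=cms["rip"], gonad=cms["gonad"], whole_animal=cms["whole_animal"],
        annotation=annotation, truth=truth, config=config,
    )
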
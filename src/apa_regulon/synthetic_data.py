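"""Synthetic tumor cohorts and RBP-depletion panels with planted ground truth.

The generator emulates the data layout of an APA regulator study: a cohort of
bulk RNA-seq samples in two (or more) conditions with variable library sizes,
a PAS count matrix over terminal exons carrying 2-3 tandem poly(A) sites, an
RBP expression matrix, CLIP binding evidence, tumor purity and progression
survival — plus a perturbation panel of control/knockdown replicate pairs.

Generative model
----------------
* Exon read totals are negative binomial with a per-exon expression factor
  and a per-sample log-normal library-size factor; within-exon PAS counts are
  multinomial.
* PAS usage proportions follow a logistic-normal: per-site logits receive
  i.i.d. Gaussian noise, so regulator effects are additive on the logit
  scale. A planted regulation (rbp, pPAS) adds
  ``-d * effect_size_logit * z_rbp`` to the proximal logit, where ``z_rbp``
  is the RBP's expression z-score and ``d`` is the depletion-response sign
  (+1 = proximal usage rises when the RBP is depleted). Condition effects on
  usage flow only through RBP expression offsets plus an optional direct
  condition shift on a disjoint set of pPAS.
* Survival is exponential with log-linear hazard in tumor purity and a
  latent per-sample APA factor that also loads on a subset of exon logits.
* Depletion experiments multiply the target RBP's expression by a knockdown
  factor and shift regulated proximal logits by ``d * effect_size_logit`` in
  the depleted arm.

One global seed drives everything; sub-streams are derived deterministically,
so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import child_rng
from .io_formats import PasAnnotation, PasCountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_perturbation_panel",
    "simulate_clip",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe the emulated study: a two-condition cohort of 60
    samples per condition, 150 terminal exons with 2-3 tandem PAS, a panel of
    20 RBPs with 30 planted regulations at logit effect 1.5, and a direct
    condition-driven shift of the same magnitude on 10% of proximal sites.
    """

    n_exons: int = 150
    pas_per_exon: tuple[int, ...] = (2, 3)
    n_samples_per_condition: int = 60
    n_conditions: int = 2
    n_rbps: int = 20
    n_true_regulations: int = 30
    effect_size_logit: float = 1.5
    condition_effect_logit: float = 1.5
    frac_condition_pas: float = 0.1
    exon_mean_count: float = 200.0
    nb_dispersion: float = 0.05
    usage_noise_sd: float = 0.25
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    rbp_condition_offset_sd: float = 0.2
    apa_factor_loading: float = 0.5
    frac_apa_loaded_exons: float = 0.2
    clip_fpr: float = 0.05
    clip_fnr: float = 0.2
    baseline_hazard: float = 0.02
    purity_coef: float = -1.5
    apa_factor_coef: float = 1.0
    censor_time: float = 120.0
    knockdown_factor: float = 0.25
    n_replicates_per_arm: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_exons", "n_samples_per_condition", "n_conditions",
                     "n_rbps", "n_replicates_per_arm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_true_regulations < 0:
            raise ValueError("n_true_regulations must be >= 0")
        if not all(k >= 2 for k in self.pas_per_exon):
            raise ValueError("pas_per_exon entries must be >= 2")
        for name in ("clip_fpr", "clip_fnr", "frac_condition_pas",
                     "frac_apa_loaded_exons"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.exon_mean_count <= 0 or self.baseline_hazard <= 0:
            raise ValueError("exon_mean_count and baseline_hazard must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of one simulated study.

    ``regulations`` rows: rbp_id, pas_id, exon_id, direction (+1 = proximal
    usage rises on depletion of the RBP, -1 = falls), direction_label.
    ``latent`` rows (one per cohort sample): condition, apa_factor, purity.
    ``condition_dapa_pas`` lists proximal sites with a planted direct
    condition shift. ``true_survival_split`` labels each sample by the sign
    of its latent APA factor (the axis survival actually depends on).
    """

    regulations: pd.DataFrame
    latent: pd.DataFrame
    condition_dapa_pas: list[str]
    true_survival_split: pd.Series
    annotations: list[PasAnnotation] = field(repr=False, default_factory=list)
    # generator internals reused by the perturbation panel
    _exon_factor: np.ndarray = field(repr=False, default=None)
    _base_logit: dict = field(repr=False, default=None)
    _apa_loading: dict = field(repr=False, default=None)
    _rbp_ids: list = field(repr=False, default_factory=list)
    _rbp_base_log2: np.ndarray = field(repr=False, default=None)
    _config: SimulationConfig = field(repr=False, default=None)


def _make_annotations(config: SimulationConfig, rng: np.random.Generator
                      ) -> list[PasAnnotation]:
    annotations = []
    for e in range(config.n_exons):
        k = int(rng.choice(config.pas_per_exon))
        strand = "+" if e % 2 == 0 else "-"
        exon_start = 10_000 * e
        exon_id = f"exon{e:04d}"
        gene_id = f"gene{e:04d}"
        # genomic positions 5'->3' on +, mirrored on -
        for rank in range(1, k + 1):
            offset = rank if strand == "+" else (k + 1 - rank)
            start = exon_start + 1000 * offset
            annotations.append(
                PasAnnotation(
                    pas_id=f"{exon_id}:pas{rank}",
                    exon_id=exon_id,
                    gene_id=gene_id,
                    chrom="chr1",
                    start=start,
                    end=start + 1,
                    strand=strand,
                    rank_from_5p=rank,
                    is_distal=(rank == k),
                )
            )
    return annotations


def _pas_logits(
    annotations: list[PasAnnotation],
    base_logit: dict,
    extra_logit: dict,
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, tuple[list[PasAnnotation], np.ndarray]]:
    """Per-exon (k x n_samples) logit matrices: base + planted shifts + noise."""
    by_exon: dict[str, list[PasAnnotation]] = {}
    for a in annotations:
        by_exon.setdefault(a.exon_id, []).append(a)
    out = {}
    for exon_id, anns in by_exon.items():
        anns = sorted(anns, key=lambda a: a.rank_from_5p)
        logits = np.empty((len(anns), n_samples))
        for i, a in enumerate(anns):
            row = np.full(n_samples, base_logit[a.pas_id], dtype=float)
            if a.pas_id in extra_logit:
                row = row + extra_logit[a.pas_id]
            row += rng.normal(0.0, noise_sd, size=n_samples)
            logits[i] = row
        out[exon_id] = (anns, logits)
    return out


def _counts_from_logits(
    exon_logits: dict,
    exon_factor: np.ndarray,
    lib_factor: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    annotations: list[PasAnnotation],
    sample_ids: list[str],
) -> PasCountMatrix:
    exon_index = {a.exon_id: i for i, a in enumerate(
        {a.exon_id: a for a in annotations}.values())}
    n_samples = len(sample_ids)
    rows = {}
    alpha = config.nb_dispersion
    for exon_id, (anns, logits) in exon_logits.items():
        mu = config.exon_mean_count * exon_factor[exon_index[exon_id]] * lib_factor
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        totals = rng.negative_binomial(n_param, p_param)
        # softmax over the exon's PAS per sample
        z = logits - logits.max(axis=0, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=0, keepdims=True)
        counts = rng.multinomial(totals, probs.T)  # (n_samples, k)
        for i, a in enumerate(anns):
            rows[a.pas_id] = counts[:, i]
    counts_df = pd.DataFrame(
        {pid: rows[pid] for pid in [a.pas_id for a in annotations]},
        index=sample_ids,
    ).T
    return PasCountMatrix(annotations=list(annotations), counts=counts_df)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[PasCountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a tumor cohort with planted RBP regulations.

    Returns (pas_counts, rbp_expression, clinical, truth). ``rbp_expression``
    is log2-scale, RBP x samples. ``clinical`` has sample_id, time, event,
    purity, subtype (the condition label).
    """
    cfg = config
    ann_rng = child_rng(cfg.seed, "annotations")
    annotations = _make_annotations(cfg, ann_rng)
    proximal = [a for a in annotations if not a.is_distal]

    n_samples = cfg.n_samples_per_condition * cfg.n_conditions
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    condition = np.repeat(np.arange(cfg.n_conditions), cfg.n_samples_per_condition)

    struct_rng = child_rng(cfg.seed, "structure")
    exon_ids = sorted({a.exon_id for a in annotations})
    exon_factor = struct_rng.lognormal(0.0, 0.5, size=len(exon_ids))
    base_logit = {a.pas_id: struct_rng.normal(0.0, 0.5) for a in annotations}
    loaded = struct_rng.random(len(exon_ids)) < cfg.frac_apa_loaded_exons
    apa_loading = {}
    for exon_id, is_loaded in zip(exon_ids, loaded):
        apa_loading[exon_id] = cfg.apa_factor_loading if is_loaded else 0.0

    # planted regulations: distinct (rbp, proximal PAS) pairs
    rbp_ids = [f"RBP{r:02d}" for r in range(cfg.n_rbps)]
    max_pairs = cfg.n_rbps * len(proximal)
    if cfg.n_true_regulations > max_pairs:
        raise ValueError(
            f"n_true_regulations={cfg.n_true_regulations} exceeds available "
            f"(rbp, proximal PAS) pairs ({max_pairs})"
        )
    reg_rng = child_rng(cfg.seed, "regulations")
    pair_idx = reg_rng.choice(max_pairs, size=cfg.n_true_regulations, replace=False)
    regulations = []
    regulated_pas = set()
    for idx in sorted(pair_idx):
        rbp = rbp_ids[idx // len(proximal)]
        pas = proximal[idx % len(proximal)]
        d = int(reg_rng.choice([-1, 1]))
        regulations.append(
            {
                "rbp_id": rbp,
                "pas_id": pas.pas_id,
                "exon_id": pas.exon_id,
                "direction": d,
                "direction_label": (
                    "proximal-up-on-depletion" if d > 0 else
                    "proximal-down-on-depletion"
                ),
            }
        )
        regulated_pas.add(pas.pas_id)
    regulations = pd.DataFrame(
        regulations,
        columns=["rbp_id", "pas_id", "exon_id", "direction", "direction_label"],
    )

    # direct condition-driven dAPA on proximal sites not tied to any RBP
    free_proximal = [a.pas_id for a in proximal if a.pas_id not in regulated_pas]
    n_cond = int(round(cfg.frac_condition_pas * len(proximal)))
    n_cond = min(n_cond, len(free_proximal))
    condition_dapa_pas = sorted(
        reg_rng.choice(free_proximal, size=n_cond, replace=False).tolist()
    )

    # RBP expression (log2 scale) with condition offsets
    expr_rng = child_rng(cfg.seed, "rbp_expression")
    rbp_base_log2 = expr_rng.normal(6.0, 1.0, size=cfg.n_rbps)
    cond_offsets = expr_rng.normal(
        0.0, cfg.rbp_condition_offset_sd, size=(cfg.n_rbps, cfg.n_conditions)
    )
    log2_expr = (
        rbp_base_log2[:, None]
        + cond_offsets[:, condition]
        + expr_rng.normal(0.0, 1.0, size=(cfg.n_rbps, n_samples))
    )
    rbp_expression = pd.DataFrame(log2_expr, index=rbp_ids, columns=sample_ids)
    z = (log2_expr - log2_expr.mean(axis=1, keepdims=True)) / log2_expr.std(
        axis=1, keepdims=True
    )
    z_by_rbp = dict(zip(rbp_ids, z))

    # latent sample factors
    latent_rng = child_rng(cfg.seed, "latent")
    apa_factor = latent_rng.normal(0.0, 1.0, size=n_samples)
    purity = latent_rng.beta(5.0, 2.0, size=n_samples)

    # assemble per-PAS extra logits
    extra_logit: dict[str, np.ndarray] = {}
    for _, reg in regulations.iterrows():
        shift = -reg["direction"] * cfg.effect_size_logit * z_by_rbp[reg["rbp_id"]]
        extra_logit[reg["pas_id"]] = extra_logit.get(reg["pas_id"], 0.0) + shift
    cond_is_one = (condition == 1).astype(float) if cfg.n_conditions > 1 else 0.0
    for pas_id in condition_dapa_pas:
        extra_logit[pas_id] = (
            extra_logit.get(pas_id, 0.0) + cfg.condition_effect_logit * cond_is_one
        )
    ann_by_id = {a.pas_id: a for a in annotations}
    for exon_id, loading in apa_loading.items():
        if loading == 0.0:
            continue
        for a in annotations:
            if a.exon_id == exon_id and not a.is_distal:
                extra_logit[a.pas_id] = (
                    extra_logit.get(a.pas_id, 0.0) + loading * apa_factor
                )

    noise_rng = child_rng(cfg.seed, "cohort_noise")
    exon_logits = _pas_logits(
        annotations, base_logit, extra_logit, n_samples, cfg.usage_noise_sd, noise_rng
    )
    lib_rng = child_rng(cfg.seed, "cohort_library")
    mu_l, sd_l = cfg.library_size_lognormal
    lib_factor = lib_rng.lognormal(mu_l, sd_l, size=n_samples)
    count_rng = child_rng(cfg.seed, "cohort_counts")
    pas_counts = _counts_from_logits(
        exon_logits, exon_factor, lib_factor, cfg, count_rng, annotations, sample_ids
    )

    # survival: exponential hazard, administrative censoring
    surv_rng = child_rng(cfg.seed, "survival")
    hazard = cfg.baseline_hazard * np.exp(
        cfg.purity_coef * purity + cfg.apa_factor_coef * apa_factor
    )
    raw_time = surv_rng.exponential(1.0 / hazard)
    time = np.minimum(raw_time, cfg.censor_time)
    event = (raw_time <= cfg.censor_time).astype(int)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "purity": purity,
            "subtype": [f"cond{c}" for c in condition],
        }
    )

    latent = pd.DataFrame(
        {"condition": condition, "apa_factor": apa_factor, "purity": purity},
        index=sample_ids,
    )
    split = pd.Series(
        apa_factor > np.median(apa_factor), index=sample_ids, name="high_apa_factor"
    )
    truth = GroundTruth(
        regulations=regulations,
        latent=latent,
        condition_dapa_pas=condition_dapa_pas,
        true_survival_split=split,
        annotations=annotations,
        _exon_factor=exon_factor,
        _base_logit=base_logit,
        _apa_loading=apa_loading,
        _rbp_ids=rbp_ids,
        _rbp_base_log2=rbp_base_log2,
        _config=cfg,
    )
    return pas_counts, rbp_expression, clinical, truth


def simulate_perturbation_panel(
    config: SimulationConfig,
    truth: GroundTruth,
    cell_line: str = "K562",
) -> tuple[PasCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate one cell line's depletion panel: one experiment per RBP.

    Returns (pas_counts, expression_counts, design). Each experiment carries
    ``n_replicates_per_arm`` control and depleted replicates; the target
    RBP's expression is multiplied by ``knockdown_factor`` in the depleted
    arm, and every regulation of that RBP shifts its proximal logit by
    ``direction * effect_size_logit`` there.
    """
    cfg = config
    if truth.annotations is None or truth._base_logit is None:
        raise ValueError("truth must come from simulate_cohort with the same config")
    annotations = truth.annotations
    rbp_ids = truth._rbp_ids
    n_rep = cfg.n_replicates_per_arm

    design_rows = []
    sample_ids = []
    for r, rbp in enumerate(rbp_ids):
        exp_id = f"{cell_line}_{rbp}"
        for arm in ("control", "depleted"):
            for rep in range(1, n_rep + 1):
                sid = f"{exp_id}_{arm}_{rep}"
                sample_ids.append(sid)
                design_rows.append(
                    {
                        "experiment_id": exp_id,
                        "cell_line": cell_line,
                        "target_rbp": rbp,
                        "sample_id": sid,
                        "arm": arm,
                        "replicate": rep,
                    }
                )
    design = pd.DataFrame(design_rows)
    n_samples = len(sample_ids)
    depleted = (design["arm"] == "depleted").to_numpy()
    target = design["target_rbp"].to_numpy()

    # planted usage shifts in depleted arms
    extra_logit: dict[str, np.ndarray] = {}
    for _, reg in truth.regulations.iterrows():
        mask = depleted & (target == reg["rbp_id"])
        shift = reg["direction"] * cfg.effect_size_logit * mask.astype(float)
        extra_logit[reg["pas_id"]] = extra_logit.get(reg["pas_id"], 0.0) + shift

    noise_rng = child_rng(cfg.seed, f"panel_noise_{cell_line}")
    exon_logits = _pas_logits(
        annotations, truth._base_logit, extra_logit, n_samples,
        cfg.usage_noise_sd, noise_rng,
    )
    lib_rng = child_rng(cfg.seed, f"panel_library_{cell_line}")
    mu_l, sd_l = cfg.library_size_lognormal
    lib_factor = lib_rng.lognormal(mu_l, sd_l, size=n_samples)
    count_rng = child_rng(cfg.seed, f"panel_counts_{cell_line}")
    pas_counts = _counts_from_logits(
        exon_logits, truth._exon_factor, lib_factor, cfg, count_rng, annotations,
        sample_ids,
    )

    # RBP expression as counts: lognormal gene mean, NB sampling, knockdown
    expr_rng = child_rng(cfg.seed, f"panel_expression_{cell_line}")
    gene_mean = 2.0 ** truth._rbp_base_log2
    mu = gene_mean[:, None] * lib_factor[None, :]
    kd = np.ones((len(rbp_ids), n_samples))
    for g, rbp in enumerate(rbp_ids):
        kd[g, depleted & (target == rbp)] = cfg.knockdown_factor
    mu = mu * kd
    n_param = 1.0 / cfg.nb_dispersion
    expr_counts = expr_rng.negative_binomial(n_param, n_param / (n_param + mu))
    expression = pd.DataFrame(expr_counts, index=rbp_ids, columns=sample_ids)
    return pas_counts, expression, design


def simulate_clip(
    truth: GroundTruth,
    clip_fpr: float | None = None,
    clip_fnr: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """CLIP binding table: true (rbp, host exon) pairs thinned by the false-
    negative rate, false pairs added at the false-positive rate."""
    cfg = truth._config
    fpr = cfg.clip_fpr if clip_fpr is None else clip_fpr
    fnr = cfg.clip_fnr if clip_fnr is None else clip_fnr
    if not (0.0 <= fpr <= 1.0 and 0.0 <= fnr <= 1.0):
        raise ValueError("clip rates must lie in [0, 1]")
    rng = child_rng(cfg.seed if seed is None else seed, "clip")

    true_pairs = set(
        zip(truth.regulations["rbp_id"], truth.regulations["exon_id"])
    )
    exon_ids = sorted({a.exon_id for a in truth.annotations})
    rows = []
    for rbp in truth._rbp_ids:
        for exon_id in exon_ids:
            is_true = (rbp, exon_id) in true_pairs
            keep = rng.random() < ((1.0 - fnr) if is_true else fpr)
            if keep:
                rows.append({"rbp_id": rbp, "exon_id": exon_id})
    return pd.DataFrame(rows, columns=["rbp_id", "exon_id"])
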
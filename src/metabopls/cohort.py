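"""Synthetic LC-MS cohort generator with full ground truth.

Emulates a single-batch plasma metabolomics run of the kind the pipeline
analyzes: a features × samples peak table of log-normal intensities with

* a planted subset of class-discriminative features whose log-mean is
  shifted between outcome groups by a known standardized effect size,
  with alternating effect signs (both protective and risk markers occur);
* correlated feature blocks driven by shared latent factors (metabolites
  from one pathway co-vary);
* smooth multiplicative intensity drift over injection order;
* pooled-QC injections — per-feature study mean perturbed by a per-feature
  technical CV — interleaved every ``qc_every`` study samples, with QCs at
  the start and end of the run, and optional blanks at the end;
* study samples injected in random order.

Defaults reproduce the cohort geometry of the motivating study: 226 polar
features, 48 study samples split 26 (creatinine <= 1.5 mg/dL) versus 22
(> 1.5 mg/dL), and a pooled QC every 6 study injections. Everything the
generator decides is returned as a :class:`GroundTruth` so recovery
experiments can score the analysis against the planted answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PeakTableError
from .peaks import PeakTable, SampleMetadata


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-design and noise parameters of the simulated cohort.

    ``effect_size`` is the planted standardized mean difference in
    log-intensity units (class 1 minus class 0, in units of the feature's
    log-SD). ``noise_cv_range`` is the range the per-feature technical CV
    on QC replicates is drawn from; the default spans 5–45% so a realistic
    share of features fails a 30% QC-CV filter. ``within_class_sd``
    multiplies the biological (within-class) variation; 0 switches it off
    for exactness checks. ``log_mean_range``/``log_sd_range`` set the
    baseline natural-log intensity distribution.
    """

    n_class0: int = 26
    n_class1: int = 22
    n_features: int = 226
    n_discriminative: int = 12
    effect_size: float = 1.2
    block_size: int = 8
    block_rho: float = 0.3
    drift_amplitude: float = 0.3
    qc_every: int = 6
    noise_cv_range: tuple = (0.05, 0.45)
    n_blank: int = 0
    missing_rate: float = 0.0
    within_class_sd: float = 1.0
    log_mean_range: tuple = (9.0, 14.0)
    log_sd_range: tuple = (0.2, 0.6)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_class0", "n_class1", "n_features", "block_size", "qc_every"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name}: must be a positive count")
        if not 0 <= self.n_discriminative <= self.n_features:
            raise ConfigError("n_discriminative: must lie in [0, n_features]")
        if self.effect_size < 0:
            raise ConfigError("effect_size: must be >= 0")
        if not 0 <= self.block_rho < 1:
            raise ConfigError("block_rho: must lie in [0, 1)")
        if self.drift_amplitude < 0 or self.drift_amplitude >= 1:
            raise ConfigError("drift_amplitude: must lie in [0, 1)")
        lo, hi = self.noise_cv_range
        if lo < 0 or hi < lo:
            raise ConfigError("noise_cv_range: must be 0 <= low <= high")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate: must lie in [0, 1)")
        if self.within_class_sd < 0:
            raise ConfigError("within_class_sd: must be >= 0")
        if self.n_blank < 0:
            raise ConfigError("n_blank: must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    discriminative_ids: list
    effect_signs: dict  # feature_id -> +1 / -1
    technical_cv: dict  # feature_id -> CV of QC replicates
    log_mean: dict  # feature_id -> baseline natural-log mean
    log_sd: dict  # feature_id -> natural-log SD
    drift_curves: pd.DataFrame = field(repr=False)  # features x injection orders
    config: CohortSimConfig = None

    def to_json(self, path=None) -> str:
        payload = {
            "discriminative_ids": list(self.discriminative_ids),
            "effect_signs": {k: int(v) for k, v in self.effect_signs.items()},
            "technical_cv": self.technical_cv,
            "log_mean": self.log_mean,
            "log_sd": self.log_sd,
            "drift_curves": {
                str(fid): row.tolist() for fid, row in self.drift_curves.iterrows()
            },
            "injection_orders": [int(c) for c in self.drift_curves.columns],
            "config": self.config.to_dict() if self.config else None,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _injection_sequence(study_ids: list, qc_every: int) -> list:
    """QC at the run start, after every ``qc_every`` study injections, and
    at the run end; returns the full sequence of (kind, id) pairs."""
    seq = [("qc", None)]
    for i, sid in enumerate(study_ids, start=1):
        seq.append(("study", sid))
        if i % qc_every == 0:
            seq.append(("qc", None))
    if seq[-1][0] != "qc":
        seq.append(("qc", None))
    # number the QCs
    out, k = [], 0
    for kind, sid in seq:
        if kind == "qc":
            k += 1
            out.append(("qc", f"QC{k:02d}"))
        else:
            out.append((kind, sid))
    return out


def _lognormal_factor(rng, cv: np.ndarray, size) -> np.ndarray:
    """Multiplicative noise with unit mean and exact CV ``cv`` (lognormal)."""
    sigma2 = np.log1p(np.asarray(cv) ** 2)
    sigma = np.sqrt(sigma2)
    return np.exp(rng.standard_normal(size) * sigma - sigma2 / 2.0)


def generate_cohort(config: CohortSimConfig):
    """Simulate a peak table, its run metadata and the ground truth.

    Deterministic given ``config`` (including its seed). Study intensities
    are exp(log-normal); pooled-QC rows are the per-feature mean of the
    study samples perturbed by that feature's technical CV; drift then
    multiplies every injection by a smooth per-feature factor of injection
    order.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_class0 + cfg.n_class1
    p = cfg.n_features

    feature_ids = [f"M{j + 1:03d}" for j in range(p)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    y = np.concatenate([np.zeros(cfg.n_class0), np.ones(cfg.n_class1)])

    # feature annotations (plausible placeholders; the analysis ignores them)
    mz = np.round(rng.uniform(70.0, 650.0, size=p), 6)
    rt = np.round(rng.uniform(0.5, 16.0, size=p), 3)
    mode = np.where(rng.random(p) < 150 / 226, "pos", "neg")
    features = pd.DataFrame(
        {
            "compound": [f"metabolite_{j + 1:03d}" for j in range(p)],
            "formula": [
                f"C{rng.integers(2, 21)}H{rng.integers(4, 33)}N{rng.integers(0, 5)}"
                f"O{rng.integers(0, 7)}"
                for _ in range(p)
            ],
            "mz": mz,
            "rt": rt,
            "mode": mode,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    mu = rng.uniform(*cfg.log_mean_range, size=p)
    sigma = rng.uniform(*cfg.log_sd_range, size=p)
    cv = rng.uniform(*cfg.noise_cv_range, size=p)

    disc_idx = np.sort(rng.choice(p, size=cfg.n_discriminative, replace=False))
    signs = np.array([1 if k % 2 == 0 else -1 for k in range(cfg.n_discriminative)])

    # within-class variation: shared block factor + independent residual.
    # blocks partition the NON-discriminative features (consecutive groups),
    # so within-block correlation is exactly block_rho; planted features
    # stay independent of the blocks.
    z = np.zeros((p, n))
    non_disc = np.setdiff1d(np.arange(p), disc_idx)
    eps = rng.standard_normal((p, n))
    for b_start in range(0, len(non_disc), cfg.block_size):
        members = non_disc[b_start : b_start + cfg.block_size]
        g = rng.standard_normal(n)
        z[members] = np.sqrt(cfg.block_rho) * g + np.sqrt(1 - cfg.block_rho) * eps[
            members
        ]
    z[disc_idx] = eps[disc_idx]

    log_int = mu[:, None] + cfg.within_class_sd * sigma[:, None] * z
    shift = signs[:, None] * cfg.effect_size * sigma[disc_idx, None]
    log_int[disc_idx] = log_int[disc_idx] + shift * y[None, :]
    study = np.exp(log_int)  # features x study samples (pre-drift)

    # injection sequence: randomized study order, QCs interleaved
    study_order = [sample_ids[i] for i in rng.permutation(n)]
    seq = _injection_sequence(study_order, cfg.qc_every)
    qc_ids = [sid for kind, sid in seq if kind == "qc"]
    blank_ids = [f"BL{k + 1:02d}" for k in range(cfg.n_blank)]
    all_ids = [sid for _, sid in seq] + blank_ids
    orders = {sid: o + 1 for o, sid in enumerate(all_ids)}

    # pooled QC rows: study mean with technical noise (unit-mean lognormal)
    qc_base = study.mean(axis=1)
    qc_vals = qc_base[:, None] * _lognormal_factor(rng, cv[:, None], (p, len(qc_ids)))

    # blanks: trace carryover near zero
    blank_vals = (
        0.01 * qc_base[:, None] * _lognormal_factor(rng, np.full((p, 1), 0.3), (p, cfg.n_blank))
        if cfg.n_blank
        else np.zeros((p, 0))
    )

    intens = pd.DataFrame(index=features.index, columns=all_ids, dtype=float)
    intens.loc[:, sample_ids] = study
    intens.loc[:, qc_ids] = qc_vals
    if blank_ids:
        intens.loc[:, blank_ids] = blank_vals

    # smooth per-feature multiplicative drift over injection order
    n_orders = len(all_ids)
    order_grid = np.arange(1, n_orders + 1, dtype=float)
    phase = rng.uniform(0, 2 * np.pi, size=p)
    freq = rng.uniform(0.5, 1.5, size=p)
    amp = cfg.drift_amplitude * rng.uniform(0.5, 1.0, size=p)
    rel = (order_grid - 1) / max(n_orders - 1, 1)
    curves = 1.0 + amp[:, None] * np.sin(2 * np.pi * freq[:, None] * rel + phase[:, None])
    drift = pd.DataFrame(curves, index=features.index, columns=order_grid.astype(int))
    order_vec = np.array([orders[sid] for sid in all_ids])
    intens = intens * curves[:, order_vec - 1]

    if cfg.missing_rate > 0:
        mask = rng.random(intens.shape) < cfg.missing_rate
        intens = intens.mask(mask)

    meta = pd.DataFrame(
        {
            "injection_order": [orders[sid] for sid in all_ids],
            "sample_type": [
                "study" if sid in set(sample_ids) else ("qc" if sid in set(qc_ids) else "blank")
                for sid in all_ids
            ],
            "outcome_label": [
                y[sample_ids.index(sid)] if sid in set(sample_ids) else np.nan
                for sid in all_ids
            ],
        },
        index=pd.Index(all_ids, name="sample_id"),
    )

    table = PeakTable(features, intens)
    metadata = SampleMetadata(meta)
    truth = GroundTruth(
        discriminative_ids=[feature_ids[j] for j in disc_idx],
        effect_signs={feature_ids[j]: int(s) for j, s in zip(disc_idx, signs)},
        technical_cv={feature_ids[j]: float(cv[j]) for j in range(p)},
        log_mean={feature_ids[j]: float(mu[j]) for j in range(p)},
        log_sd={feature_ids[j]: float(sigma[j]) for j in range(p)},
        drift_curves=drift,
        config=cfg,
    )
    return table, metadata, truth


def inject_drift(table: PeakTable, metadata: SampleMetadata, drift_spec) -> PeakTable:
    """Multiply each intensity by a positive factor of its injection order.

    ``drift_spec`` is either a callable ``order -> factor`` or a mapping
    from injection order to factor. Feature annotations are unchanged.
    """
    orders = metadata.injection_order(table.sample_ids)
    if callable(drift_spec):
        factors = np.array([drift_spec(o) for o in orders], dtype=float)
    else:
        try:
            factors = np.array([drift_spec[int(o)] for o in orders], dtype=float)
        except KeyError as exc:
            raise PeakTableError(f"drift_spec missing injection order {exc}") from exc
    if np.any(factors <= 0) or np.any(~np.isfinite(factors)):
        raise PeakTableError("drift factors must be positive and finite")
    return table.with_intensities(table.intensities.to_numpy(dtype=float) * factors)


def pool_qc(
    table: PeakTable,
    metadata: SampleMetadata,
    qc_every: int = 6,
    noise_cv: float = 0.0,
    seed: int | None = None,
):
    """Append pooled-QC rows to a study-only table.

    Each QC's expected intensity per feature is the mean over the study
    samples, optionally perturbed by a unit-mean lognormal with CV
    ``noise_cv``. QCs are placed at the run start, after every ``qc_every``
    study injections, and at the run end. Returns the augmented
    ``(PeakTable, SampleMetadata)``.
    """
    study_ids = [s for s in metadata.study_ids if s in table.intensities.columns]
    if not study_ids:
        raise PeakTableError("pool_qc needs at least one study sample")
    if qc_every < 1:
        raise ConfigError("qc_every: must be a positive count")
    order_sorted = sorted(study_ids, key=lambda s: metadata.frame.loc[s, "injection_order"])
    seq = _injection_sequence(order_sorted, qc_every)
    qc_ids = [sid for kind, sid in seq if kind == "qc"]
    base = table.intensities[study_ids].to_numpy(dtype=float).mean(axis=1)
    p = table.n_features
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        qc_vals = base[:, None] * _lognormal_factor(
            rng, np.full((p, 1), float(noise_cv)), (p, len(qc_ids))
        )
    else:
        qc_vals = np.repeat(base[:, None], len(qc_ids), axis=1)
    intens = pd.concat(
        [
            table.intensities.copy(),
            pd.DataFrame(qc_vals, index=table.features.index, columns=qc_ids),
        ],
        axis=1,
    )
    new_meta = metadata.frame.copy()
    orders = {sid: o + 1 for o, (kind, sid) in enumerate(seq)}
    for sid in table.sample_ids:
        if sid in orders:
            new_meta.loc[sid, "injection_order"] = orders[sid]
    qc_rows = pd.DataFrame(
        {
            "injection_order": [orders[q] for q in qc_ids],
            "sample_type": "qc",
            "outcome_label": np.nan,
        },
        index=pd.Index(qc_ids, name="sample_id"),
    )
    meta = SampleMetadata(pd.concat([new_meta.loc[list(table.sample_ids)], qc_rows]))
    return PeakTable(table.features.copy(), intens), meta


def planted_effect_estimate(
    table: PeakTable, metadata: SampleMetadata, truth: GroundTruth
) -> pd.Series:
    """Per planted feature, the empirical class difference of mean
    log-intensity standardized by the generator's log-SD (the realized
    effect size, on the pre-drift scale only if drift is off)."""
    study = metadata.study_ids
    y = metadata.outcome(study)
    vals = table.intensities[study].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log(vals)
    idx = [table.feature_ids.index(f) for f in truth.discriminative_ids]
    out = {}
    for f, j in zip(truth.discriminative_ids, idx):
        diff = logv[j, y == 1].mean() - logv[j, y == 0].mean()
        out[f] = diff / truth.log_sd[f]
    return pd.Series(out, name="standardized_log_difference")
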
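"""Synthetic data with known ground truth for every pipeline input.

Two generators cover the two halves of the pipeline.

**Coverage**: a circular bacterial chromosome replicating bidirectionally
from a single origin has expected read depth ``mean_depth``-scaled
``ptr**(1 - x)``, where ``x`` in [0, 1] is the circular distance from the
origin divided by half the genome length and ``ptr`` is the true
peak-to-trough coverage ratio.  Per-base depths are drawn Poisson around
that expectation (or emitted exactly), and the genome is fragmented
left-to-right into contigs, mimicking assembly.

**Cohort**: covariates (baseline BMI, age, sex, weight-loss group) are drawn
first; each feature then follows the generative model the association
framework assumes — a linear predictor ``intercept + beta_bmi*(BMI - mean) +
beta_wl*group + beta_sex*sex`` realised as Gaussian noise on the log scale
(continuous analytes), a negative-binomial count with per-sample library
size (sequencing counts), or a latent Gaussian cut into the 0-8 ordinal
scale (diet frequencies).  Weights consistent with each subject's group are
generated so the cohort-selection rules re-derive the simulated labels.

Every generator is a pure function of its config, seed included; truth
tables record every nonzero effect so downstream classifications can be
scored without reaching into generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageSimConfig",
    "CohortSimConfig",
    "simulate_coverage",
    "simulate_taxa",
    "simulate_cohort",
]

TAXON_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class CoverageSimConfig:
    """Ground-truth description of one replicating genome's coverage."""

    genome_length: int = 2_000_000
    origin_index: int = 0
    true_ptr: float = 2.0
    mean_depth: float = 20.0
    noise: str = "poisson"
    contig_lengths: Sequence[int] = field(default_factory=lambda: [50_000])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ptr < 1.0:
            raise ValueError("true_ptr must be >= 1")
        if sum(self.contig_lengths) > self.genome_length:
            raise ValueError("contig lengths exceed genome length")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"noise must be 'poisson' or 'none', got {self.noise!r}")


def _expected_depth(cfg: CoverageSimConfig) -> np.ndarray:
    pos = np.arange(cfg.genome_length)
    d = np.abs(pos - cfg.origin_index)
    circ = np.minimum(d, cfg.genome_length - d)
    x = circ / (cfg.genome_length / 2.0)
    m = cfg.true_ptr ** (1.0 - x)
    return cfg.mean_depth * m / m.mean()


def simulate_coverage(
    config: CoverageSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-contig depth tables plus a truth record.

    Returns ``(tables, truth)`` where ``tables`` maps contig id to a
    DepthTable DataFrame (``contig_id, position`` 1-based, ``depth``) and
    ``truth`` records per contig the genome interval it came from and the
    expected local coverage span (max/min expected depth over the contig).
    """
    rng = np.random.default_rng(config.seed)
    expected = _expected_depth(config)
    if config.noise == "poisson":
        depth = rng.poisson(expected).astype(float)
    else:
        depth = expected.copy()

    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    start = 0
    for k, length in enumerate(config.contig_lengths):
        cid = f"contig_{k}"
        sub = depth[start : start + length]
        exp_sub = expected[start : start + length]
        tables[cid] = pd.DataFrame(
            {
                "contig_id": cid,
                "position": np.arange(1, length + 1),
                "depth": sub,
            }
        )
        truth_rows.append(
            {
                "contig_id": cid,
                "genome_start": start,
                "length": length,
                "true_ptr": config.true_ptr,
                "expected_min": exp_sub.min(),
                "expected_max": exp_sub.max(),
                "expected_span": exp_sub.max() / exp_sub.min(),
            }
        )
        start += length
    return tables, pd.DataFrame(truth_rows)


def simulate_taxa(
    contig_ids: Sequence[str],
    phylum_proportions: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Random phylum assignment of contigs; key ``"NA"`` = unclassified.

    Proportions must sum to 1.  Unclassified contigs carry empty strings in
    every rank; classified contigs get a phylum (and a superkingdom of
    Bacteria), leaving lower ranks unclassified, matching the sparse output
    of marker-gene contig classifiers.
    """
    labels = list(phylum_proportions)
    probs = np.array([phylum_proportions[k] for k in labels], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"proportions must sum to 1, got {probs.sum()}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(labels), size=len(contig_ids), p=probs)
    rows = []
    for cid, idx in zip(contig_ids, chosen):
        phylum = labels[idx]
        row = {rank: "" for rank in TAXON_RANKS}
        row["contig_id"] = cid
        if phylum != "NA":
            row["superkingdom"] = "Bacteria"
            row["phylum"] = phylum
        rows.append(row)
    return pd.DataFrame(rows, columns=["contig_id", *TAXON_RANKS])


@dataclass
class CohortSimConfig:
    """Cohort sizes, covariate distributions, and per-feature effects.

    Defaults mirror the study conditions: 105 subjects of whom 48/105 are in
    the weight-loss group, an overweight middle-aged cohort (baseline BMI
    ~N(30, 5) kg/m2, age ~N(50, 10) y, sexes balanced).  ``feature_specs``
    rows need ``feature_id`` and ``kind`` (continuous_log / ordinal /
    count); optional columns ``beta_bmi`` (effect per BMI unit on the model
    scale), ``beta_wl`` (group effect), ``beta_sex``, ``intercept``,
    ``noise_sd`` (Gaussian/latent sd, default 1.0) and ``dispersion`` (NB2
    alpha, default 0.1).
    """

    n_subjects: int = 105
    group_fraction: float = 48 / 105
    bmi_mean: float = 30.0
    bmi_sd: float = 5.0
    age_mean: float = 50.0
    age_sd: float = 10.0
    feature_specs: pd.DataFrame | None = None
    library_size_range: tuple[int, int] = (150_000, 400_000)
    n_zero_variance: int = 0
    seed: int = 0


def _spec_col(specs: pd.DataFrame, name: str, default: float) -> np.ndarray:
    if name in specs.columns:
        return specs[name].fillna(default).to_numpy(dtype=float)
    return np.full(len(specs), default)


def simulate_cohort(config: CohortSimConfig) -> dict[str, pd.DataFrame]:
    """Metadata, one feature matrix per kind, and the truth table.

    Returns a dict with keys ``metadata``, ``continuous_log``, ``ordinal``,
    ``count`` (matrices only for kinds present in ``feature_specs``) and
    ``truth`` (feature_id, term, true_beta for every nonzero effect).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_wl = int(round(config.group_fraction * n))
    subject_ids = [f"S{i:04d}" for i in range(n)]
    group = np.array(["weight_loss"] * n_wl + ["no_weight_loss"] * (n - n_wl))
    rng.shuffle(group)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n).clip(min=16.0)
    age = rng.normal(config.age_mean, config.age_sd, n).clip(min=20.0)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    g = (group == "weight_loss").astype(float)
    s = (sex == "male").astype(float)

    # weights consistent with the group labels so selection re-derives them
    height = rng.normal(1.70, 0.08, n)
    baseline_weight = bmi * height**2
    months = rng.uniform(6.0, 12.0, n)
    rate = np.where(
        g == 1.0, rng.uniform(-3.0, -1.05, n), rng.uniform(0.0, 0.095, n)
    )
    followup_weight = baseline_weight * (1.0 + rate / 100.0 * months)

    meta = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "age": np.round(age, 1),
            "baseline_bmi": np.round(bmi, 2),
            "baseline_weight": np.round(baseline_weight, 2),
            "followup_weight": np.round(followup_weight, 2),
            "months_between": np.round(months, 2),
            "group": group,
        }
    )
    if config.n_zero_variance:
        stale = []
        for k in range(config.n_zero_variance):
            w = float(np.round(rng.uniform(60, 110), 1))
            stale.append(
                {
                    "subject_id": f"Z{k:04d}",
                    "sex": "female" if k % 2 else "male",
                    "age": 50.0,
                    "baseline_bmi": 30.0,
                    "baseline_weight": w,
                    "followup_weight": w,
                    "months_between": 8.0,
                    "group": "excluded",
                    "weight_series": ";".join([str(w)] * 3),
                }
            )
        meta = pd.concat([meta, pd.DataFrame(stale)], ignore_index=True)

    out: dict[str, pd.DataFrame] = {"metadata": meta}
    specs = config.feature_specs
    if specs is None or len(specs) == 0:
        out["truth"] = pd.DataFrame(columns=["feature_id", "term", "true_beta"])
        return out

    bmi_c = bmi - config.bmi_mean
    beta_bmi = _spec_col(specs, "beta_bmi", 0.0)
    beta_wl = _spec_col(specs, "beta_wl", 0.0)
    beta_sex = _spec_col(specs, "beta_sex", 0.0)
    intercept = _spec_col(specs, "intercept", 0.0)
    noise_sd = _spec_col(specs, "noise_sd", 1.0)
    dispersion = _spec_col(specs, "dispersion", 0.1)
    eta = (
        intercept[:, None]
        + np.outer(beta_bmi, bmi_c)
        + np.outer(beta_wl, g)
        + np.outer(beta_sex, s)
    )

    truth_rows = []
    for i, fid in enumerate(specs["feature_id"]):
        for term, beta in (
            ("baseline_bmi", beta_bmi[i]),
            ("weight_loss", beta_wl[i]),
            ("sex", beta_sex[i]),
        ):
            if beta != 0.0:
                truth_rows.append(
                    {"feature_id": fid, "term": term, "true_beta": beta}
                )
    out["truth"] = pd.DataFrame(
        truth_rows, columns=["feature_id", "term", "true_beta"]
    )

    kinds = specs["kind"].to_numpy()
    lib = rng.integers(*config.library_size_range, size=n)

    idx_cont = np.where(kinds == "continuous_log")[0]
    if len(idx_cont):
        vals = eta[idx_cont] + rng.normal(
            0.0, noise_sd[idx_cont][:, None], (len(idx_cont), n)
        )
        out["continuous_log"] = pd.DataFrame(
            vals, index=specs["feature_id"].iloc[idx_cont], columns=subject_ids
        )

    idx_ord = np.where(kinds == "ordinal")[0]
    if len(idx_ord):
        latent = eta[idx_ord] + rng.normal(
            0.0, noise_sd[idx_ord][:, None], (len(idx_ord), n)
        )
        ordinal = np.empty_like(latent, dtype=np.int64)
        for r in range(len(idx_ord)):
            # equal-quantile cuts of the latent variable onto the 0-8 scale
            edges = np.quantile(latent[r], np.linspace(0, 1, 10)[1:-1])
            ordinal[r] = np.searchsorted(edges, latent[r], side="right")
        out["ordinal"] = pd.DataFrame(
            ordinal, index=specs["feature_id"].iloc[idx_ord], columns=subject_ids
        )

    idx_count = np.where(kinds == "count")[0]
    if len(idx_count):
        # shared per-sample library-size factor exercises the size-factor path
        sf = lib / lib.mean()
        mu = sf[None, :] * np.exp(eta[idx_count])
        # dispersion 0 is drawn as NB with a tiny alpha (numerically Poisson)
        disp = np.maximum(dispersion[idx_count][:, None], 1e-8)
        size = 1.0 / disp
        counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)
        out["count"] = pd.DataFrame(
            counts, index=specs["feature_id"].iloc[idx_count], columns=subject_ids
        )
    return out
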
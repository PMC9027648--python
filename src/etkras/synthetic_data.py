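"""Synthetic paired RNA/protein data for the 2x2 genotype x exposure design.

The generator emulates the shape of the study this package models: four
conditions (WT/MUT genotype crossed with control/chronic-ethanol exposure),
a single RNA-seq library per condition, three proteomic replicates per
condition, ~3,000 proteins nested inside ~20,000 transcripts, and missing
protein values.  Every planted fact — differentially expressed features,
sign-flip hub edges, subtype signature blocks, cross-omics coupling — is
recorded in a :class:`TruthRecord` so each downstream stage can be verified
against known ground truth.

Model summary
-------------
* Transcript counts: negative binomial with per-feature log-normal base
  means, fixed dispersion, and per-sample library size factors.
* Protein reporter ratios: log-normal around 1.  Within a condition the
  replicate-to-replicate variation has two parts: a coordinated component
  along a shared (batch-like) replicate axis, with per-feature loadings
  whose signs persist across conditions, and idiosyncratic log2-noise
  ``protein_sigma``.  The coordinated component mirrors how real replicate
  covariance is dominated by a few shared axes; it also means
  between-feature correlations keep a consistent sign across conditions,
  so sign-flip network edges do not arise by chance (with only three
  replicates, independent noise alone would exceed |r| = 0.75 in roughly
  half of all pairs).
* Planted differential expression: a fixed |log2 fold change| applied to
  the MUT+treated condition, on transcripts and on their protein-coding
  subset.
* Hub edges: within each condition the hub and its partners load on a
  latent replicate factor orthogonal to the background axis; the partner's
  loading sign is the configured edge sign in the focal (MUT+treated)
  condition and the opposite sign elsewhere, producing the sign-flip
  correlation pattern while staying uncorrelated with the background.
* Cross-omics coupling: per-condition coordinated log2 deviations shared
  between transcript and protein profiles with configurable strength.
* Subtype signatures: four disjoint protein blocks carrying per-condition
  effects (default: Proliferative and Metabolic up, Inflammatory down in
  MUT+treated).

Features carrying planted structure are exempt from random missingness;
otherwise the planted facts would not be recoverable by construction and
tests against the truth record would measure the missingness process, not
the analysis code.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iokit import DEFAULT_CONDITIONS, OmicsMatrix, SampleMeta

SUBTYPE_CLASSES = ("Proliferative", "Inflammatory", "Metabolic", "Progenitor-like")

#: (genotype, exposure) for each default condition label
CONDITION_DESIGN = {
    "HPNE": ("WT", "control"),
    "HPNE_EtOH": ("WT", "treated"),
    "HPNE_KRAS": ("MUT", "control"),
    "HPNE_KRAS_EtOH": ("MUT", "treated"),
}


@dataclass(frozen=True)
class HubSpec:
    """One planted hub: ``hub_id`` (None = auto-assign a feature),
    number of partners and the edge sign class in the focal condition."""

    hub_id: str | None = None
    n_partners: int = 20
    sign: str = "positive"

    def __post_init__(self) -> None:
        if self.n_partners < 2:
            raise ValueError("n_partners must be >= 2")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")


@dataclass
class SimulationConfig:
    """Parameters of the paired-omics generator.

    Defaults emulate the modelled study: 3,000 proteins, 20,000 transcripts,
    3 proteomic replicates and one RNA library per condition, planted
    |log2FC| = 1.5 on 5% of features in MUT+treated, one positive-edge hub
    with 20 partners, and cross-omics coupling strongest in MUT+treated.
    """

    seed: int = 0
    n_proteins: int = 3000
    n_transcripts: int = 20000
    n_replicates: int = 3
    rna_replicates: int = 1
    de_fraction: float = 0.05
    de_log2fc: float = 1.5
    hub_spec: tuple[HubSpec, ...] = (HubSpec(n_partners=20, sign="positive"),)
    missing_rate: float = 0.05
    coupling: tuple[float, ...] = (0.3, 0.3, 0.3, 0.8)
    coupling_sd: float = 0.15
    subtype_signal: Mapping[str, tuple[float, float, float, float]] | None = None
    subtype_block_size: int = 15
    library_size_factors: tuple[float, ...] | None = None
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    protein_sigma: float = 0.05
    bg_axis_scale: float = 0.15
    rna_dispersion: float = 0.1
    rna_log_mean: float = 4.6
    rna_log_sd: float = 1.2
    hub_amp: float = 1.5
    hub_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("de_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0.0 <= c <= 1.0 for c in self.coupling):
            raise ValueError("coupling strengths must be in [0, 1]")
        if len(self.coupling) != len(self.conditions):
            raise ValueError("coupling needs one value per condition")
        if self.n_proteins > self.n_transcripts:
            raise ValueError("n_proteins may not exceed n_transcripts")
        if self.hub_spec and self.n_replicates < 3:
            raise ValueError(
                "hub_spec requires >= 3 replicates: correlation over fewer "
                "points is degenerate"
            )
        self.hub_spec = tuple(
            h if isinstance(h, HubSpec) else HubSpec(*h) for h in self.hub_spec
        )
        if self.subtype_signal is None:
            focal = self.focal_condition
            self.subtype_signal = {
                c: (2.0, -2.0, 2.0, 0.0) if c == focal else (0.0, 0.0, 0.0, 0.0)
                for c in self.conditions
            }
        if self.library_size_factors is None:
            base = (1.0, 1.25, 0.8, 1.0)
            n_rna = len(self.conditions) * self.rna_replicates
            self.library_size_factors = tuple(
                base[i % len(base)] for i in range(n_rna)
            )

    @property
    def focal_condition(self) -> str:
        """The MUT+treated condition (last label by convention)."""
        return self.conditions[-1]


@dataclass
class TruthRecord:
    """Ledger of every planted fact, keyed the way downstream tests need it."""

    de_features: dict[str, float]            # feature -> log2FC in focal vs MUT control
    hub_edges: list[tuple[str, str, str]]    # (hub, partner, sign_class)
    hub_ids: list[str]
    subtype_labels: dict[str, str]           # protein sample -> planted dominant class
    signature_features: dict[str, list[str]] # class -> feature block
    coupling: dict[str, float]               # condition -> coupling strength
    library_size_factors: dict[str, float]   # rna sample -> configured factor
    missing_exempt: list[str]
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hub_edges"] = [list(e) for e in self.hub_edges]
        return d


def _feature_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def _sample_meta(conditions: Sequence[str], n_rep: int, suffix: str) -> list[SampleMeta]:
    metas = []
    for cond in conditions:
        geno, expo = CONDITION_DESIGN.get(cond, ("WT", "control"))
        for r in range(1, n_rep + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"{cond}_{suffix}{r}",
                    condition=cond,
                    genotype=geno,
                    exposure=expo,
                    replicate=r,
                )
            )
    return metas


def simulate_multiomics(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, TruthRecord]:
    """Generate paired RNA and protein matrices with recorded ground truth.

    Returns ``(rna, protein, truth)``.  All randomness derives from
    ``config.seed``; identical configs give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    conds = list(cfg.conditions)
    n_cond = len(conds)
    focal = cfg.focal_condition
    mut_control = conds[-2] if n_cond >= 2 else conds[0]

    features = _feature_ids(cfg.n_transcripts)
    protein_features = features[: cfg.n_proteins]

    # ---- reserve disjoint feature blocks for planted structure ------------
    order = rng.permutation(cfg.n_proteins)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        idx = order[cursor : cursor + k]
        if len(idx) < k:
            raise ValueError("not enough protein features for planted structure")
        cursor += k
        return list(idx)

    signature_idx: dict[str, list[int]] = {
        cls: take(cfg.subtype_block_size) for cls in SUBTYPE_CLASSES
    }
    hub_rows: list[tuple[int, list[int], str, str]] = []  # (hub_idx, partner_idx, sign, hub_id)
    for spec in cfg.hub_spec:
        if spec.hub_id is not None and spec.hub_id in features:
            hub_idx = features.index(spec.hub_id)
        elif spec.hub_id is not None:
            raise ValueError(f"hub_id {spec.hub_id!r} is not a generated feature")
        else:
            hub_idx = take(1)[0]
        partners = take(spec.n_partners)
        hub_rows.append((hub_idx, partners, spec.sign, features[hub_idx]))

    reserved = set()
    for idxs in signature_idx.values():
        reserved.update(idxs)
    for hub_idx, partners, _, _ in hub_rows:
        reserved.add(hub_idx)
        reserved.update(partners)

    # ---- planted DE (focal vs MUT control), outside reserved rows --------
    n_de = int(round(cfg.de_fraction * cfg.n_transcripts))
    candidates = np.array([i for i in range(cfg.n_transcripts) if i not in reserved])
    de_idx = rng.choice(candidates, size=n_de, replace=False) if n_de else np.array([], int)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    de_lfc = np.zeros(cfg.n_transcripts)
    de_lfc[de_idx] = de_sign * cfg.de_log2fc

    # ---- cross-omics coupling: per-condition coordinated log2 deviations -
    # u drives the transcript side; the protein side mixes u with an
    # independent draw v so that corr(u, w) = coupling within each condition.
    u = rng.normal(0.0, cfg.coupling_sd, size=(cfg.n_proteins, n_cond))
    v = rng.normal(0.0, cfg.coupling_sd, size=(cfg.n_proteins, n_cond))
    coupling = np.asarray(cfg.coupling)
    w = u * coupling + v * np.sqrt(1.0 - coupling**2)

    # subtype signature effects are transcriptional programs: planted in
    # both assays (features x conditions, log2)
    subtype_log2 = np.zeros((cfg.n_proteins, n_cond))
    for cls_i, cls in enumerate(SUBTYPE_CLASSES):
        rows = signature_idx[cls]
        for ci, cond in enumerate(conds):
            subtype_log2[rows, ci] += cfg.subtype_signal[cond][cls_i]

    # ---- RNA counts -------------------------------------------------------
    rna_meta = _sample_meta(conds, cfg.rna_replicates, "R")
    n_rna = len(rna_meta)
    if len(cfg.library_size_factors) != n_rna:
        raise ValueError("library_size_factors must match the RNA sample count")
    base_mu = rng.lognormal(cfg.rna_log_mean, cfg.rna_log_sd, size=cfg.n_transcripts)
    rna_cols = {}
    disp = cfg.rna_dispersion
    nb_n = 1.0 / disp
    for j, meta in enumerate(rna_meta):
        ci = conds.index(meta.condition)
        log2_shift = de_lfc * (meta.condition == focal)
        mu = base_mu * np.exp2(log2_shift)
        mu[: cfg.n_proteins] *= np.exp2(u[:, ci] + subtype_log2[:, ci])
        mu = mu * cfg.library_size_factors[j]
        p = nb_n / (nb_n + mu)
        rna_cols[meta.sample_id] = rng.negative_binomial(nb_n, p).astype(float)
    rna_df = pd.DataFrame(rna_cols, index=features)
    rna = OmicsMatrix(values=rna_df, assay="rna_counts", samples=rna_meta)

    # ---- protein ratios ---------------------------------------------------
    prot_meta = _sample_meta(conds, cfg.n_replicates, "P")
    n_rep = cfg.n_replicates
    log2p = np.zeros((cfg.n_proteins, len(prot_meta)))
    col_cond = np.array([conds.index(m.condition) for m in prot_meta])
    for j, ci in enumerate(col_cond):
        log2p[:, j] = (
            w[:, ci]
            + subtype_log2[:, ci]
            + de_lfc[: cfg.n_proteins] * (conds[ci] == focal)
        )

    # coordinated replicate variation: per condition, a shared zero-sum
    # replicate axis g with signed per-feature loadings whose sign persists
    # across conditions; the hub latent factor f is orthogonal to g (and to
    # the mean), so hub machinery is uncorrelated with the background.
    bg_loading = (
        rng.uniform(0.7, 1.3, size=cfg.n_proteins)
        * rng.choice([-1.0, 1.0], size=cfg.n_proteins)
        * cfg.bg_axis_scale
    )
    axes: dict[int, tuple[np.ndarray, np.ndarray | None]] = {}
    for ci in range(n_cond):
        M = rng.normal(size=(n_rep, min(n_rep, 3)))
        M[:, 0] = 1.0
        Q, _ = np.linalg.qr(M)
        g = Q[:, 1] if n_rep >= 2 else np.zeros(n_rep)
        f = Q[:, 2] if n_rep >= 3 else None
        axes[ci] = (g, f)
        cols = np.where(col_cond == ci)[0]
        log2p[:, cols] += np.outer(bg_loading, g * np.sqrt(n_rep))
    log2p += rng.normal(0.0, cfg.protein_sigma, size=log2p.shape)

    # hub machinery overwrites its rows: latent factor on the axis
    # orthogonal to the background, partner sign flipped in the focal
    # condition
    hub_edges: list[tuple[str, str, str]] = []
    for hub_idx, partners, sign, hub_id in hub_rows:
        s_edge = 1.0 if sign == "positive" else -1.0
        for ci, cond in enumerate(conds):
            cols = np.where(col_cond == ci)[0]
            f = axes[ci][1] * np.sqrt(n_rep)
            s_partner = s_edge if cond == focal else -s_edge
            log2p[hub_idx, cols] = cfg.hub_amp * f + rng.normal(
                0.0, cfg.hub_noise_sd, size=len(cols)
            )
            for p_idx in partners:
                log2p[p_idx, cols] = s_partner * cfg.hub_amp * f + rng.normal(
                    0.0, cfg.hub_noise_sd, size=len(cols)
                )
        for p_idx in partners:
            hub_edges.append((hub_id, features[p_idx], sign))

    prot = np.exp2(log2p)

    # ---- missingness (planted-structure rows exempt) ----------------------
    de_protein = set(int(i) for i in de_idx if i < cfg.n_proteins)
    exempt = reserved | de_protein
    if cfg.missing_rate > 0:
        mask = rng.random(prot.shape) < cfg.missing_rate
        mask[sorted(exempt), :] = False
        prot[mask] = np.nan

    prot_df = pd.DataFrame(
        prot, index=protein_features, columns=[m.sample_id for m in prot_meta]
    )
    protein = OmicsMatrix(values=prot_df, assay="protein_ratio", samples=prot_meta)

    # ---- truth ------------------------------------------------------------
    subtype_labels = {}
    for m in prot_meta:
        sig = cfg.subtype_signal[m.condition]
        subtype_labels[m.sample_id] = (
            SUBTYPE_CLASSES[int(np.argmax(sig))] if max(sig) > 0 else "none"
        )
    # the focal-vs-MUT-control fold change ledger includes the signature
    # blocks: their planted condition effects are real differential
    # expression in that contrast
    de_map = {features[int(i)]: float(de_lfc[int(i)]) for i in de_idx}
    for cls_i, cls in enumerate(SUBTYPE_CLASSES):
        delta = (cfg.subtype_signal[focal][cls_i]
                 - cfg.subtype_signal[mut_control][cls_i])
        if delta != 0.0:
            for i in signature_idx[cls]:
                fid = protein_features[i]
                de_map[fid] = de_map.get(fid, 0.0) + float(delta)
    truth = TruthRecord(
        de_features=de_map,
        hub_edges=hub_edges,
        hub_ids=[hid for *_, hid in hub_rows],
        subtype_labels=subtype_labels,
        signature_features={
            cls: [protein_features[i] for i in idxs]
            for cls, idxs in signature_idx.items()
        },
        coupling=dict(zip(conds, map(float, coupling))),
        library_size_factors={
            m.sample_id: float(cfg.library_size_factors[j])
            for j, m in enumerate(rna_meta)
        },
        missing_exempt=[protein_features[i] for i in sorted(exempt) if i < cfg.n_proteins],
        seed=cfg.seed,
    )
    return rna, protein, truth


def simulate_reference_cohort(
    config: SimulationConfig,
    n_per_class: int = 10,
    class_effect: float = 2.0,
    seed: int | None = None,
) -> tuple[OmicsMatrix, dict[str, str]]:
    """Labelled protein cohort for training a subtype signature model.

    Each class's samples elevate that class's signature block by
    ``class_effect`` log2 units over log-normal noise; the feature space is
    identical to :func:`simulate_multiomics` output so models trained here
    can score the paired cell-line matrices.  Returns (matrix, labels).
    """
    cfg = config
    rng_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(rng_seed)
    # reproduce the same reserved-block layout as simulate_multiomics
    block_rng = np.random.default_rng(cfg.seed)
    order = block_rng.permutation(cfg.n_proteins)
    protein_features = _feature_ids(cfg.n_transcripts)[: cfg.n_proteins]
    signature_idx = {
        cls: list(order[i * cfg.subtype_block_size : (i + 1) * cfg.subtype_block_size])
        for i, cls in enumerate(SUBTYPE_CLASSES)
    }

    metas: list[SampleMeta] = []
    labels: dict[str, str] = {}
    cols = {}
    for cls in SUBTYPE_CLASSES:
        short = cls.split("-")[0][:6]
        for i in range(1, n_per_class + 1):
            sid = f"REF_{short}_{i}"
            metas.append(
                SampleMeta(sample_id=sid, condition=f"REF_{cls}",
                           genotype="WT", exposure="control", replicate=i)
            )
            labels[sid] = cls
            log2 = rng.normal(0.0, cfg.protein_sigma, size=cfg.n_proteins)
            log2[signature_idx[cls]] += class_effect
            cols[sid] = np.exp2(log2)
    df = pd.DataFrame(cols, index=protein_features)
    return OmicsMatrix(values=df, assay="protein_ratio", samples=metas), labels


def simulate_growth(
    rate_per_hour: float,
    n0: float,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential growth curve with multiplicative log-normal noise.

    ``counts = n0 * exp(rate * t)`` perturbed by log-normal noise whose
    coefficient of variation is ``noise_cv``.  Returns columns
    ``time_h, cells``.
    """
    if not np.isfinite(rate_per_hour):
        raise ValueError("rate must be finite")
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    counts = n0 * np.exp(rate_per_hour * t)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        rng = np.random.default_rng(seed)
        counts = counts * np.exp(rng.normal(-sigma**2 / 2, sigma, size=t.shape))
    return pd.DataFrame({"time_h": t, "cells": counts})
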
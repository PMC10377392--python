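"""Synthetic study inputs with the statistical structure the pipeline assumes.

Two kinds of data live here:

* **Simulators** that draw a full input bundle — annotation catalogue,
  cell-line and tumor expression matrices, drug-target map, clinical and
  IHC tables — from a :class:`SimulationConfig`. Expression is generated
  directly on a normalized log scale (Gaussian gene baselines plus
  sample noise), with a planted high-expression subset of surfaceome
  genes, HPV effects on a fraction of surfaceome genes, tier-dependent
  glycosylation-motif probabilities, per-class drug-association rates,
  and exponential survival whose hazard depends on the high/low
  expression group of one designated marker gene. Every generator is a
  pure function of the config (seed included): per-generator random
  substreams are derived from the one seed, so adding a generator never
  perturbs the others.

* **Exact fixtures** (:func:`fixture_reference_tables`) — deterministic
  gene-level tables whose marginals equal published summary tables for
  the motif-by-quartile comparison, the p16-by-HPV cross-tab, and the
  per-class druggability counts, so those statistics can be recomputed
  from reconstructed inputs rather than copied.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .clinical import (
    IHC_MARKERS,
    ClinicalRecord,
    IHCRecord,
    clinical_to_frame,
    ihc_to_frame,
)
from .reference import (
    Catalogue,
    DrugTargetMap,
    GeneAnnotation,
    write_catalogue,
    write_drug_table,
)
from .summarize import ExpressionDataset, SampleMeta, write_expression

MARKER_GENES = ("BSG", "FGFR1", "SLC16A1")

_SUBCLASS_VOCAB = {
    "Receptors": ("GPCR", "IG", "SCAR", "RTK"),
    "Transporters": ("SLC", "Channels", "ABC"),
    "Enzymes": ("Kinase", "Protease"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults emulating its scale.

    Expression values are unitless log-scale intensities. ``high_shift``
    is expressed in units of ``baseline_sd``; ``hpv_effect_size`` in
    units of ``tumor_noise_sd``. ``survival_baseline_hazard`` and
    ``censor_hazard`` are per-month exponential hazards;
    ``survival_log_hr`` is the log hazard ratio of the marker-high
    group.
    """

    seed: int = 0
    n_genes: int = 20000
    n_surfaceome: int = 2886
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Receptors": 0.25,
            "Transporters": 0.18,
            "Enzymes": 0.07,
            "Miscellaneous": 0.16,
            "Unclassified": 0.34,
        }
    )
    n_cell_lines: int = 5  # each arrayed in duplicate
    n_tumors: int = 18
    n_hpv_pos: int = 10
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    line_effect_sd: float = 0.5
    cell_line_noise_sd: float = 0.3
    tumor_noise_sd: float = 1.0
    planted_high_fraction: float = 0.25
    high_shift: float = 2.5
    hpv_effect_size: float = 2.0
    hpv_effect_fraction: float = 0.2
    motif_prob_high: Mapping[str, float] = field(
        default_factory=lambda: {"O": 0.22, "C": 0.20, "noncyt_nxst": 0.97}
    )
    motif_prob_low: Mapping[str, float] = field(
        default_factory=lambda: {"O": 0.10, "C": 0.19, "noncyt_nxst": 0.94}
    )
    drug_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "Receptors": 0.23,
            "Transporters": 0.22,
            "Enzymes": 0.21,
            "Miscellaneous": 0.01,
            "Unclassified": 0.06,
        }
    )
    compounds_per_hit: float = 3.0
    survival_baseline_hazard: float = math.log(2) / 54.5
    survival_log_hr: float = math.log(4)
    censor_hazard: float = 0.005
    marker_gene: str = "BSG"

    def __post_init__(self) -> None:
        if not 0 <= self.n_hpv_pos <= self.n_tumors:
            raise ValueError("n_hpv_pos must lie in [0, n_tumors]")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for probs in (self.motif_prob_high, self.motif_prob_low, self.drug_rate):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_surfaceome > self.n_genes:
            raise ValueError("n_surfaceome cannot exceed n_genes")
        if self.n_surfaceome < len(MARKER_GENES):
            raise ValueError(f"n_surfaceome must be >= {len(MARKER_GENES)}")


# Substream indices: one per generator, so outputs are independent and
# adding a generator never changes another's draws.
_STREAMS = {
    "catalogue": 0,
    "planted": 1,
    "baseline": 2,
    "cell_lines": 3,
    "tumors": 4,
    "clinical": 5,
    "drugs": 6,
    "ihc": 7,
    "hpv_effects": 8,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


def gene_symbols(config: SimulationConfig) -> list[str]:
    """Deterministic gene naming: surfaceome genes first, markers leading."""
    surf = list(MARKER_GENES) + [
        f"SURF{i:05d}" for i in range(len(MARKER_GENES) + 1, config.n_surfaceome + 1)
    ]
    rest = [f"GENE{i:05d}" for i in range(1, config.n_genes - config.n_surfaceome + 1)]
    return surf + rest


def surfaceome_symbols(config: SimulationConfig) -> list[str]:
    return gene_symbols(config)[: config.n_surfaceome]


def planted_high_genes(config: SimulationConfig) -> frozenset[str]:
    """The surfaceome subset given a high-expression shift.

    The three marker genes are always planted (they are picked for IHC
    and survival follow-up precisely because they are top-tier); the
    remainder is a seeded draw from the other surfaceome genes.
    """
    surf = surfaceome_symbols(config)
    n_planted = max(
        len(MARKER_GENES), int(round(config.planted_high_fraction * len(surf)))
    )
    pool = surf[len(MARKER_GENES):]
    rng = _rng(config, "planted")
    extra = rng.choice(len(pool), size=n_planted - len(MARKER_GENES), replace=False)
    return frozenset(MARKER_GENES) | frozenset(pool[i] for i in sorted(extra))


def simulate_catalogue(config: SimulationConfig) -> Catalogue:
    """Draw a surfaceome annotation catalogue.

    Exactly ``n_surfaceome`` genes are flagged as surfaceome members;
    their Almen main classes follow ``class_proportions`` and motif
    flags are Bernoulli with tier-dependent probabilities (planted-high
    genes use ``motif_prob_high``). The marker genes carry their
    field-standard classes (BSG unclassified immunoglobulin-superfamily
    partner, FGFR1 receptor, SLC16A1 transporter).
    """
    rng = _rng(config, "catalogue")
    planted = planted_high_genes(config)
    symbols = gene_symbols(config)
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    forced_class = {"BSG": "Unclassified", "FGFR1": "Receptors",
                    "SLC16A1": "Transporters"}
    forced_sub = {"FGFR1": "RTK", "SLC16A1": "SLC"}

    annotations = []
    for i, sym in enumerate(symbols):
        if i >= config.n_surfaceome:
            annotations.append(GeneAnnotation(symbol=sym, is_surfaceome=False))
            continue
        main = forced_class.get(sym, classes[rng.choice(len(classes), p=probs)])
        if sym in forced_sub:
            sub = forced_sub[sym]
        else:
            vocab = _SUBCLASS_VOCAB.get(main)
            sub = (
                vocab[rng.integers(len(vocab))]
                if vocab is not None and rng.random() < 0.6
                else None
            )
        motif_probs = (
            config.motif_prob_high if sym in planted else config.motif_prob_low
        )
        annotations.append(
            GeneAnnotation(
                symbol=sym,
                is_surfaceome=True,
                almen_main=main,
                almen_sub=sub,
                glycomineO_present=bool(rng.random() < motif_probs["O"]),
                glycomineC_present=bool(rng.random() < motif_probs["C"]),
                noncyt_nxst_present=bool(rng.random() < motif_probs["noncyt_nxst"]),
            )
        )
    return Catalogue(annotations)


def _gene_baselines(config: SimulationConfig) -> pd.Series:
    """Shared per-gene log-expression baselines (planted shift applied)."""
    rng = _rng(config, "baseline")
    symbols = gene_symbols(config)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(symbols))
    planted = planted_high_genes(config)
    shift = config.high_shift * config.baseline_sd
    mu += np.array([shift if s in planted else 0.0 for s in symbols])
    return pd.Series(mu, index=pd.Index(symbols, name="symbol"))


def simulate_cell_lines(
    config: SimulationConfig, catalogue: Optional[Catalogue] = None
) -> ExpressionDataset:
    """Cell-line matrix: ``n_cell_lines`` lines arrayed in duplicate.

    Each line adds a biological effect shared by its two technical
    replicate columns; replicate columns differ only by technical noise
    (``cell_line_noise_sd``), so duplicates correlate strongly across
    genes. All lines are HPV-negative.
    """
    rng = _rng(config, "cell_lines")
    mu = _gene_baselines(config)
    n_genes = len(mu)
    columns: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    for line in range(1, config.n_cell_lines + 1):
        line_effect = rng.normal(0.0, config.line_effect_sd, size=n_genes)
        for rep in ("a", "b"):
            sample_id = f"CL{line}_{rep}"
            noise = rng.normal(0.0, config.cell_line_noise_sd, size=n_genes)
            columns[sample_id] = mu.to_numpy() + line_effect + noise
            metas.append(
                SampleMeta(
                    sample_id=sample_id,
                    dataset_id="cell_lines",
                    hpv_status="neg",
                    replicate_group=f"CL{line}",
                )
            )
    values = pd.DataFrame(columns, index=mu.index)
    return ExpressionDataset(
        values=values, samples=tuple(metas), dataset_id="cell_lines"
    )


def hpv_effect_genes(config: SimulationConfig) -> dict[str, float]:
    """Surfaceome genes given an HPV-positive shift, with signed effects."""
    rng = _rng(config, "hpv_effects")
    surf = surfaceome_symbols(config)
    n_affected = int(round(config.hpv_effect_fraction * len(surf)))
    idx = rng.choice(len(surf), size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    shift = config.hpv_effect_size * config.tumor_noise_sd
    return {surf[i]: float(s * shift) for i, s in zip(sorted(idx), signs)}


def simulate_tumors(
    config: SimulationConfig, catalogue: Optional[Catalogue] = None
) -> tuple[ExpressionDataset, list[ClinicalRecord]]:
    """Tumor cohort: expression matrix plus matched clinical records.

    HPV-positive samples receive signed expression shifts on the
    ``hpv_effect_fraction`` of surfaceome genes drawn by
    :func:`hpv_effect_genes`. Survival times are exponential with a
    hazard multiplied by ``exp(survival_log_hr)`` for patients in the
    marker gene's high-expression half; censoring is an independent
    exponential clock. p16 is positive for every HPV-positive patient.
    """
    rng = _rng(config, "tumors")
    effects = hpv_effect_genes(config)
    mu = _gene_baselines(config)
    n_genes = len(mu)
    n_neg = config.n_tumors - config.n_hpv_pos

    columns: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    statuses: list[str] = []
    for i in range(1, config.n_tumors + 1):
        status = "neg" if i <= n_neg else "pos"
        sample_id = f"T{i:02d}"
        vals = mu.to_numpy() + rng.normal(0.0, config.tumor_noise_sd, size=n_genes)
        if status == "pos" and effects:
            for sym, eff in effects.items():
                vals[mu.index.get_loc(sym)] += eff
        columns[sample_id] = vals
        statuses.append(status)
        metas.append(
            SampleMeta(sample_id=sample_id, dataset_id="tumors", hpv_status=status)
        )
    values = pd.DataFrame(columns, index=mu.index)
    dataset = ExpressionDataset(values=values, samples=tuple(metas),
                                dataset_id="tumors")
    records = _simulate_clinical(config, dataset, statuses)
    return dataset, records


_HISTOLOGIES = ("Usual", "Basaloid", "Warty", "Verrucous", "Mixed", "Other")


def _simulate_clinical(
    config: SimulationConfig,
    tumors: ExpressionDataset,
    statuses: list[str],
) -> list[ClinicalRecord]:
    rng = _rng(config, "clinical")
    marker = tumors.values.loc[config.marker_gene]
    median = float(marker.median())
    records = []
    for i, (sample_id, status) in enumerate(
        zip(tumors.values.columns, statuses), start=1
    ):
        high = float(marker[sample_id]) > median
        hazard = config.survival_baseline_hazard * math.exp(
            config.survival_log_hr * high
        )
        event_time = rng.exponential(1.0 / hazard)
        censor_time = (
            rng.exponential(1.0 / config.censor_hazard)
            if config.censor_hazard > 0
            else math.inf
        )
        if status == "pos":
            p16 = "Positive"
        else:
            p16 = ("Negative", "Positive", "Unknown")[
                rng.choice(3, p=[0.75, 0.10, 0.15])
            ]
        records.append(
            ClinicalRecord(
                patient_id=sample_id,
                hpv_status=status,
                p16=p16,
                histology=_HISTOLOGIES[
                    rng.choice(len(_HISTOLOGIES),
                               p=[0.5, 0.12, 0.12, 0.12, 0.1, 0.04])
                ],
                lvi=bool(rng.random() < 0.65),
                pT=int(rng.choice([1, 2, 3], p=[0.3, 0.3, 0.4])),
                pN=int(rng.choice([0, 1, 2, 3], p=[0.25, 0.1, 0.45, 0.2])),
                age_years=float(np.round(rng.normal(58.0, 9.0), 1)),
                os_months=float(np.round(min(event_time, censor_time), 1)),
                os_event=bool(event_time <= censor_time),
            )
        )
    return records


def simulate_drug_table(
    config: SimulationConfig, catalogue: Catalogue
) -> DrugTargetMap:
    """Per-class Bernoulli drug hits; hits get 1 + Poisson compounds."""
    rng = _rng(config, "drugs")
    extra_mean = max(0.0, config.compounds_per_hit - 1.0)
    entries: dict[str, frozenset[str]] = {}
    for ann in catalogue:
        if not ann.is_surfaceome:
            continue
        rate = config.drug_rate.get(ann.main_class_label, 0.0)
        if rng.random() < rate:
            n_compounds = 1 + int(rng.poisson(extra_mean))
            entries[ann.symbol] = frozenset(
                f"DB-{ann.symbol}-{j:02d}" for j in range(1, n_compounds + 1)
            )
    return DrugTargetMap(entries)


_IHC_NUCLEAR = {"CD147": (15.0, 8.0), "FGFR1": (40.0, 15.0), "MCT1": (5.0, 4.0)}


def simulate_ihc(config: SimulationConfig, n_samples: int = 12) -> list[IHCRecord]:
    """IHC scores: ``n_samples`` tumors (HPV-balanced) x 3 markers x 2 compartments.

    Membrane percent-positive is drawn high (mean 85) for every marker;
    nuclear distributions are marker-specific, FGFR1 having the
    smallest membrane-nuclear gap (it shows the most compartment
    diversity). Intensities are strong at the membrane (2-3) and weak
    in the nucleus (0-1).
    """
    rng = _rng(config, "ihc")
    records = []
    for i in range(1, n_samples + 1):
        status = "neg" if i <= n_samples // 2 else "pos"
        for marker in IHC_MARKERS:
            mem = float(np.clip(rng.normal(85.0, 8.0), 0.0, 100.0))
            nuc_mean, nuc_sd = _IHC_NUCLEAR[marker]
            nuc = float(np.clip(rng.normal(nuc_mean, nuc_sd), 0.0, 100.0))
            records.append(
                IHCRecord(
                    sample_id=f"IHC{i:02d}",
                    marker=marker,
                    hpv_status=status,
                    compartment="membrane",
                    intensity=int(rng.choice([2, 3])),
                    percent_positive=round(mem, 1),
                )
            )
            records.append(
                IHCRecord(
                    sample_id=f"IHC{i:02d}",
                    marker=marker,
                    hpv_status=status,
                    compartment="nuclear",
                    intensity=int(rng.choice([0, 1])),
                    percent_positive=round(nuc, 1),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Exact fixtures reconstructing published summary tables


@dataclass(frozen=True)
class ReferenceTableFixtures:
    """Deterministic gene-level tables with published marginals.

    ``motif_catalogue`` holds 239 bottom-tier and 497 top-tier
    surfaceome genes whose motif-presence counts equal the published
    quartile comparison (O: 24 vs 111; C: 45 vs 97; N-X-S/T: 224 vs
    483). ``p16_records`` is an 18-patient cohort with the published
    p16-by-HPV cross-tab (6/1/1 negative-group, 0/10/0 positive-group).
    ``drug_catalogue``/``drug_map`` realize the per-class druggability
    table: (targets, total drugs, targets-with-drugs) = Receptors
    (115, 85, 27), Transporters (80, 56, 18), Unclassified (222, 25,
    14), Enzymes (33, 12, 7), Miscellaneous (69, 1, 1).
    """

    motif_catalogue: Catalogue
    tier_q1: frozenset[str]
    tier_q4: frozenset[str]
    p16_records: tuple[ClinicalRecord, ...]
    drug_catalogue: Catalogue
    drug_map: DrugTargetMap


_MOTIF_COUNTS = {  # tier -> (n, O present, C present, N-X-S/T present)
    "Q1": (239, 24, 45, 224),
    "Q4": (497, 111, 97, 483),
}

_DRUGGABILITY = {  # class -> (n targets, total drugs, targets with drugs)
    "Receptors": (115, 85, 27),
    "Transporters": (80, 56, 18),
    "Unclassified": (222, 25, 14),
    "Enzymes": (33, 12, 7),
    "Miscellaneous": (69, 1, 1),
}


def fixture_reference_tables() -> ReferenceTableFixtures:
    """Build the exact fixture bundle (byte-identical across runs)."""
    motif_annotations = []
    tiers: dict[str, frozenset[str]] = {}
    for tier, (n, n_o, n_c, n_n) in _MOTIF_COUNTS.items():
        symbols = [f"{tier}G{i:03d}" for i in range(1, n + 1)]
        tiers[tier] = frozenset(symbols)
        for i, sym in enumerate(symbols):
            motif_annotations.append(
                GeneAnnotation(
                    symbol=sym,
                    is_surfaceome=True,
                    glycomineO_present=i < n_o,
                    glycomineC_present=i < n_c,
                    noncyt_nxst_present=i < n_n,
                )
            )

    p16_records = []
    p16_layout = [("neg", "Negative", 6), ("neg", "Positive", 1),
                  ("neg", "Unknown", 1), ("pos", "Positive", 10)]
    i = 0
    for hpv, p16, count in p16_layout:
        for _ in range(count):
            i += 1
            p16_records.append(
                ClinicalRecord(
                    patient_id=f"P{i:02d}",
                    hpv_status=hpv,
                    p16=p16,
                    histology="Usual",
                    age_years=58.0,
                    os_months=24.0,
                    os_event=False,
                )
            )

    drug_annotations = []
    drug_entries: dict[str, frozenset[str]] = {}
    for cls, (n_targets, total_drugs, n_hits) in _DRUGGABILITY.items():
        prefix = cls[:4].upper()
        base, remainder = divmod(total_drugs, n_hits)
        for i in range(1, n_targets + 1):
            sym = f"{prefix}{i:03d}"
            drug_annotations.append(
                GeneAnnotation(
                    symbol=sym,
                    is_surfaceome=True,
                    almen_main=cls,
                    glycomineO_present=False,
                    glycomineC_present=False,
                    noncyt_nxst_present=False,
                )
            )
            if i <= n_hits:
                n_compounds = base + (1 if i <= remainder else 0)
                drug_entries[sym] = frozenset(
                    f"DB-{sym}-{j:02d}" for j in range(1, n_compounds + 1)
                )

    return ReferenceTableFixtures(
        motif_catalogue=Catalogue(motif_annotations),
        tier_q1=tiers["Q1"],
        tier_q4=tiers["Q4"],
        p16_records=tuple(p16_records),
        drug_catalogue=Catalogue(drug_annotations),
        drug_map=DrugTargetMap(drug_entries),
    )


# ---------------------------------------------------------------------------
# Bundle writer


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate every input and write the TSV bundle to ``outdir``.

    Writes catalogue.tsv, cell_lines.tsv (+ cell_line_samples.tsv),
    tumors.tsv (+ tumor_samples.tsv), drugs.tsv, clinical.tsv, ihc.tsv
    and a config echo (config.json). Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogue = simulate_catalogue(config)
    cell_lines = simulate_cell_lines(config, catalogue)
    tumors, clinical = simulate_tumors(config, catalogue)
    drugs = simulate_drug_table(config, catalogue)
    ihc = simulate_ihc(config)

    paths = {
        "catalogue": outdir / "catalogue.tsv",
        "cell_lines": outdir / "cell_lines.tsv",
        "cell_line_samples": outdir / "cell_line_samples.tsv",
        "tumors": outdir / "tumors.tsv",
        "tumor_samples": outdir / "tumor_samples.tsv",
        "drugs": outdir / "drugs.tsv",
        "clinical": outdir / "clinical.tsv",
        "ihc": outdir / "ihc.tsv",
        "config": outdir / "config.json",
    }
    write_catalogue(catalogue, paths["catalogue"])
    write_expression(cell_lines, paths["cell_lines"], paths["cell_line_samples"])
    write_expression(tumors, paths["tumors"], paths["tumor_samples"])
    write_drug_table(drugs, paths["drugs"])
    clinical_to_frame(clinical).to_csv(paths["clinical"], sep="\t", index=False)
    ihc_to_frame(ihc).to_csv(paths["ihc"], sep="\t", index=False)
    echo = dataclasses.asdict(config)
    echo = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in echo.items()}
    paths["config"].write_text(json.dumps(echo, indent=2, sort_keys=True))
    return paths
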
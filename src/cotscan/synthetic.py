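"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline is testable offline against planted ground
truth: signal anchor sequences (TM1-like hydrophobic cores in polar
context, optionally with a conformational consensus motif planted at a
recorded position), tripartite n/h/c signal peptides, SILAC label-swap
ratio tables with a chosen sensitive fraction and multiplicative lognormal
noise, and sigmoidal concentration-response data.

All generators are pure functions of (config, seed): repeated calls are
byte-identical, and the planted truth is always returned alongside the
data. The default cohort shape mirrors the study that motivated the
pipeline: 217 proteins, 53 secretory / 164 membrane, membrane SAS:SP split
105:56 with 3 unspecified, overall sensitive fraction 71/217.

Residue frequency tables are fixed multinomials chosen to look like
transmembrane cores and polar loops; they are not learned from databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .assay import DoseResponseParams, response
from .core import (
    DEFAULT_SCHEME,
    DoseResponseDataset,
    ProteinClass,
    ResidueClassScheme,
    SignalSequenceRecord,
    SignalType,
    SilacRatioRecord,
    Topology,
    ValidationError,
)

# Fixed multinomial for TM1-like hydrophobic cores. Strongly hydrophobic:
# small residues are kept rare so that, without planting, a full motif
# (two small patches plus an adjacent flank) is a ~few-percent event per
# core, matching the low background the screen assumes.
CORE_FREQS = {
    "L": 0.28, "I": 0.17, "V": 0.17, "F": 0.13, "A": 0.06, "M": 0.07,
    "G": 0.03, "W": 0.04, "Y": 0.01, "T": 0.02, "S": 0.02,
}
# Fixed multinomial for polar flanking context (N/C tails, loops).
POLAR_FREQS = {
    "S": 0.10, "T": 0.08, "N": 0.08, "Q": 0.08, "D": 0.08, "E": 0.09,
    "K": 0.10, "R": 0.10, "G": 0.08, "P": 0.06, "A": 0.08, "H": 0.04, "L": 0.03,
}
# Hydrophobic separator residues used when planting motifs into cores.
PLANT_SEPARATOR_RESIDUES = "LIVFMW"


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_proteins: int = 217
    fraction_secretory: float = 53 / 217
    fraction_sensitive: float = 71 / 217
    #: Optional per-class override {"secretory": p, "membrane": p}.
    fraction_sensitive_by_class: Optional[dict[str, float]] = None
    motif_prevalence_sensitive_sas: float = 1.0
    motif_prevalence_resistant_sas: float = 5 / 94
    ratio_effect_range: tuple[float, float] = (2.0, 10.0)
    ratio_noise_cv: float = 0.1
    sas_length_range: tuple[int, int] = (18, 25)
    sp_length_range: tuple[int, int] = (15, 27)

    def __post_init__(self) -> None:
        for name in ("fraction_secretory", "fraction_sensitive",
                     "motif_prevalence_sensitive_sas", "motif_prevalence_resistant_sas"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {p}")
        if not self.ratio_effect_range[0] > 1:
            raise ValidationError("sensitive effect ratios must exceed 1")
        if self.ratio_noise_cv < 0:
            raise ValidationError("ratio_noise_cv must be >= 0")


#: Study-shaped preset (217 proteins, label-swap CV 10%).
PAPERLIKE_CONFIG = GeneratorConfig(
    fraction_sensitive_by_class={"secretory": 50 / 53, "membrane": 21 / 164},
)


def _sample(rng: np.random.Generator, freqs: dict[str, float], n: int) -> str:
    letters = sorted(freqs)
    probs = np.array([freqs[l] for l in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted CCM occurrence."""

    accession: str
    patch1_start: int  # 1-based in the full sequence
    separator_length: int
    patch2_length: int
    flank_placement: str  # left | right | both


# The 12 concrete CCM geometries: (separator, patch2, flank placement).
MOTIF_GEOMETRIES = [
    (sep, p2, placement)
    for sep in (2, 3)
    for p2 in (1, 2)
    for placement in ("left", "right", "both")
]


def _plant_motif(
    core: str,
    core_start: int,
    rng: np.random.Generator,
    scheme: ResidueClassScheme,
    accession: str,
) -> tuple[str, PlantedMotif]:
    sep_len, p2_len, placement = MOTIF_GEOMETRIES[rng.integers(len(MOTIF_GEOMETRIES))]
    n_flanks = {"left": 1, "right": 1, "both": 2}[placement]
    motif_len = n_flanks + 2 + sep_len + p2_len
    if motif_len > len(core):
        raise ValidationError("core too short to plant a motif")
    offset = int(rng.integers(0, len(core) - motif_len + 1))
    small = sorted(scheme.small)
    flank = sorted(scheme.flank)
    separator_pool = sorted(set(PLANT_SEPARATOR_RESIDUES) & scheme.bulky) or sorted(scheme.bulky)
    parts = []
    if placement in ("left", "both"):
        parts.append(rng.choice(flank))
    parts.extend(rng.choice(small, size=2))
    parts.extend(rng.choice(separator_pool, size=sep_len))
    parts.extend(rng.choice(small, size=p2_len))
    if placement in ("right", "both"):
        parts.append(rng.choice(flank))
    motif = "".join(parts)
    mutated = core[:offset] + motif + core[offset + motif_len:]
    patch1_start = core_start + offset + (1 if placement in ("left", "both") else 0)
    return mutated, PlantedMotif(accession, patch1_start, sep_len, p2_len, placement)


def generate_sas(
    n: int,
    config: GeneratorConfig = GeneratorConfig(),
    rng: Optional[np.random.Generator] = None,
    motif_prevalence: Optional[float] = None,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    prefix: str = "SAS",
) -> tuple[list[SignalSequenceRecord], dict[str, Optional[PlantedMotif]]]:
    """Signal-anchor (TM1-like) membrane proteins with optional planted CCM.

    With probability ``motif_prevalence`` (default: the config's
    sensitive-SAS prevalence) one of the 12 concrete motif geometries is
    planted, wholly inside the annotated core, at a recorded position.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    prevalence = (
        motif_prevalence if motif_prevalence is not None else config.motif_prevalence_sensitive_sas
    )
    records: list[SignalSequenceRecord] = []
    truth: dict[str, Optional[PlantedMotif]] = {}
    for i in range(n):
        accession = f"{prefix}{i:04d}"
        n_tail = "M" + _sample(rng, POLAR_FREQS, int(rng.integers(3, 11)))
        core_len = int(rng.integers(config.sas_length_range[0], config.sas_length_range[1] + 1))
        core = _sample(rng, CORE_FREQS, core_len)
        c_tail = _sample(rng, POLAR_FREQS, int(rng.integers(5, 16)))
        core_start = len(n_tail) + 1
        planted: Optional[PlantedMotif] = None
        if rng.random() < prevalence:
            core, planted = _plant_motif(core, core_start, rng, scheme, accession)
        topo = (Topology.NC, Topology.NE, Topology.UNSPECIFIED)[
            int(rng.choice(3, p=[0.85, 0.05, 0.10]))
        ]
        records.append(
            SignalSequenceRecord(
                accession=accession,
                full_sequence=n_tail + core + c_tail,
                protein_class=ProteinClass.MEMBRANE,
                signal_type=SignalType.SAS,
                signal_start=core_start,
                signal_end=core_start + len(core) - 1,
                topology=topo,
            )
        )
        truth[accession] = planted
    return records, truth


def generate_sp(
    n: int,
    config: GeneratorConfig = GeneratorConfig(),
    rng: Optional[np.random.Generator] = None,
    protein_class: ProteinClass = ProteinClass.SECRETORY,
    prefix: str = "SP",
) -> list[SignalSequenceRecord]:
    """Cleavable signal peptides with tripartite n/h/c architecture.

    Positively charged n-region (1–5 residues after the initiator Met),
    hydrophobic h-region (7–15), polar c-region (3–7) ending in the
    A-X-A cleavage-site pattern. No motif is planted.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records = []
    for i in range(n):
        accession = f"{prefix}{i:04d}"
        n_len = int(rng.integers(1, 6))
        n_region = "M" + "".join(rng.choice(list("KRKQNS"), size=n_len - 1)) if n_len > 1 else "M"
        h_region = _sample(rng, CORE_FREQS, int(rng.integers(7, 16)))
        c_len = int(rng.integers(3, 8))
        c_region = _sample(rng, POLAR_FREQS, c_len)
        if c_len >= 3:
            c_region = c_region[:-3] + "A" + c_region[-2] + "A"
        signal = n_region + h_region + c_region
        mature = _sample(rng, POLAR_FREQS, 12)
        records.append(
            SignalSequenceRecord(
                accession=accession,
                full_sequence=signal + mature,
                protein_class=protein_class,
                signal_type=SignalType.SP,
                signal_start=1,
                signal_end=len(signal),
                topology=Topology.UNSPECIFIED,
            )
        )
    return records


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


@dataclass
class SilacSimulation:
    """Ratio records, planted truth labels and the raw intensity layer."""

    records: list[SilacRatioRecord]
    truth: dict[str, str]  # accession -> sensitive | resistant
    true_ratio: dict[str, float] = field(default_factory=dict)
    # Intensity layer (arbitrary units): forward experiment H = DMSO,
    # reverse experiment L = DMSO; observed ratios derive from these.
    forward_heavy: np.ndarray = field(default_factory=lambda: np.empty(0))
    forward_light: np.ndarray = field(default_factory=lambda: np.empty(0))
    reverse_heavy: np.ndarray = field(default_factory=lambda: np.empty(0))
    reverse_light: np.ndarray = field(default_factory=lambda: np.empty(0))


def generate_silac_table(
    config: GeneratorConfig = GeneratorConfig(),
    rng: Optional[np.random.Generator] = None,
    annotations: Optional[Sequence[SignalSequenceRecord]] = None,
) -> SilacSimulation:
    """Label-swap ratio table with planted sensitivity truth.

    Sensitive proteins carry a true DMSO/cotransin ratio drawn uniformly
    from ``ratio_effect_range``; resistant proteins have true ratio 1.
    Observed forward and reverse ratios multiply the true ratio by
    independent lognormal noise of the configured CV. When ``annotations``
    are given, class/type metadata (and cohort size) follow them;
    otherwise a cohort of ``n_proteins`` is drawn from the configured
    class fractions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows: list[tuple[str, ProteinClass, SignalType]] = []
    if annotations is not None:
        rows = [(r.accession, r.protein_class, r.signal_type) for r in annotations]
    else:
        for i in range(config.n_proteins):
            secretory = rng.random() < config.fraction_secretory
            cls = ProteinClass.SECRETORY if secretory else ProteinClass.MEMBRANE
            if secretory:
                styp = SignalType.SP
            else:
                u = rng.random()
                styp = (
                    SignalType.SAS if u < 105 / 164
                    else SignalType.SP if u < 161 / 164
                    else SignalType.UNSPECIFIED
                )
            rows.append((f"P{i:04d}", cls, styp))

    sim = SilacSimulation(records=[], truth={})
    fh, fl, rh, rl = [], [], [], []
    by_class = config.fraction_sensitive_by_class or {}
    for accession, cls, styp in rows:
        p_sens = by_class.get(cls.value, config.fraction_sensitive)
        sensitive = rng.random() < p_sens
        true_ratio = float(rng.uniform(*config.ratio_effect_range)) if sensitive else 1.0
        obs_f = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
        obs_r = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
        # Intensity layer: DMSO channel ~ lognormal abundance, treated
        # channel scaled so the channel quotient reproduces the ratio.
        abundance_f = float(rng.lognormal(mean=13.0, sigma=1.0))
        abundance_r = float(rng.lognormal(mean=13.0, sigma=1.0))
        fh.append(abundance_f)                # forward: H = DMSO
        fl.append(abundance_f / obs_f)        # forward: L = cotransin
        rl.append(abundance_r)                # reverse: L = DMSO
        rh.append(abundance_r / obs_r)        # reverse: H = cotransin
        sim.records.append(
            SilacRatioRecord(
                accession=accession,
                forward_ratio=obs_f,
                reverse_ratio=obs_r,
                protein_class=cls,
                signal_type=styp,
            )
        )
        sim.truth[accession] = "sensitive" if sensitive else "resistant"
        sim.true_ratio[accession] = true_ratio
    sim.forward_heavy = np.array(fh)
    sim.forward_light = np.array(fl)
    sim.reverse_heavy = np.array(rh)
    sim.reverse_light = np.array(rl)
    return sim


def generate_dose_response(
    params: DoseResponseParams,
    concentrations: Sequence[float],
    replicates: int = 3,
    cv: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> DoseResponseDataset:
    """Sigmoidal concentration-response data with lognormal replicate noise."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    conc, resp, rep = [], [], []
    for r in range(replicates):
        for c in concentrations:
            if c <= 0:
                raise ValidationError("concentrations must be positive")
            y = response(c, params) * float(_lognormal_noise(rng, cv))
            conc.append(float(c))
            resp.append(float(y))
            rep.append(r + 1)
    return DoseResponseDataset(concentration=conc, response_percent=resp, replicate=rep)


# ---------------------------------------------------------------------------
# Study-shaped fixtures

#: (protein_class, signal_type, label, count) strata of the published cohort:
#: 217 proteins; 50/53 secretory sensitive; membrane sensitive 21
#: (SP 9, SAS 11, unspecified 1); membrane non-sensitive 143
#: (SP 47, SAS 94, unspecified 2).
PAPERLIKE_STRATA: list[tuple[ProteinClass, SignalType, str, int]] = [
    (ProteinClass.SECRETORY, SignalType.SP, "sensitive", 50),
    (ProteinClass.SECRETORY, SignalType.SP, "resistant", 3),
    (ProteinClass.MEMBRANE, SignalType.SP, "sensitive", 9),
    (ProteinClass.MEMBRANE, SignalType.SAS, "sensitive", 11),
    (ProteinClass.MEMBRANE, SignalType.UNSPECIFIED, "sensitive", 1),
    (ProteinClass.MEMBRANE, SignalType.SP, "resistant", 47),
    (ProteinClass.MEMBRANE, SignalType.SAS, "resistant", 94),
    (ProteinClass.MEMBRANE, SignalType.UNSPECIFIED, "resistant", 2),
]


def paperlike_silac_table(
    seed: int = 0,
    threshold: float = 1.65,
    config: GeneratorConfig = PAPERLIKE_CONFIG,
) -> SilacSimulation:
    """Synthetic stand-in for the published SILAC supplementary table.

    The real table is only available as a PDF supplement, so this fixture
    reproduces its stratum structure exactly: each stratum's ratios are
    drawn conditionally on the corresponding side of the dual >threshold
    criterion (the published per-stratum counts are themselves defined by
    that criterion). Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    sim = SilacSimulation(records=[], truth={})
    i = 0
    for cls, styp, label, count in PAPERLIKE_STRATA:
        for _ in range(count):
            accession = f"S1-{i:03d}"
            i += 1
            for _attempt in range(1000):
                if label == "sensitive":
                    true_ratio = float(rng.uniform(*config.ratio_effect_range))
                else:
                    true_ratio = 1.0
                obs_f = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
                obs_r = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
                is_sensitive = obs_f > threshold and obs_r > threshold
                if is_sensitive == (label == "sensitive"):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("rejection sampling failed")
            sim.records.append(
                SilacRatioRecord(accession, obs_f, obs_r, protein_class=cls, signal_type=styp)
            )
            sim.truth[accession] = label
            sim.true_ratio[accession] = true_ratio
    return sim


@dataclass
class StudyData:
    """A full simulated study: sequences, ratios and all planted truth."""

    sequences: list[SignalSequenceRecord]
    ratios: list[SilacRatioRecord]
    sensitivity_truth: dict[str, str]
    motif_truth: dict[str, Optional[PlantedMotif]]
    config: GeneratorConfig


def generate_study(config: GeneratorConfig = PAPERLIKE_CONFIG) -> StudyData:
    """Simulate a coherent cohort for the whole pipeline.

    Sensitivity labels are drawn per class; motifs are planted in SAS
    cores at the configured sensitive/resistant prevalences; SPs carry no
    motif. Ratio tables are generated from the same labels, so the
    classifier, the motif screen and the enrichment test all see one
    consistent synthetic study.
    """
    rng = np.random.default_rng(config.seed)
    n_secretory = round(config.n_proteins * config.fraction_secretory)
    n_membrane = config.n_proteins - n_secretory
    n_mem_sas = round(n_membrane * 105 / 164)
    n_mem_unspec = min(n_membrane - n_mem_sas, max(0, round(n_membrane * 3 / 164)))
    n_mem_sp = n_membrane - n_mem_sas - n_mem_unspec

    by_class = config.fraction_sensitive_by_class or {}
    p_secr = by_class.get("secretory", config.fraction_sensitive)
    p_mem = by_class.get("membrane", config.fraction_sensitive)

    sequences: list[SignalSequenceRecord] = []
    motif_truth: dict[str, Optional[PlantedMotif]] = {}
    sensitivity: dict[str, str] = {}

    sp_secr = generate_sp(n_secretory, config, rng, ProteinClass.SECRETORY, prefix="SEC")
    for rec in sp_secr:
        sensitivity[rec.accession] = "sensitive" if rng.random() < p_secr else "resistant"
        motif_truth[rec.accession] = None
    sequences.extend(sp_secr)

    sp_mem = generate_sp(n_mem_sp, config, rng, ProteinClass.MEMBRANE, prefix="MSP")
    for rec in sp_mem:
        sensitivity[rec.accession] = "sensitive" if rng.random() < p_mem else "resistant"
        motif_truth[rec.accession] = None
    sequences.extend(sp_mem)

    # SAS labels drawn first so the motif prevalence can depend on them.
    for i in range(n_mem_sas):
        accession = f"SAS{i:04d}"
        sensitivity[accession] = "sensitive" if rng.random() < p_mem else "resistant"
    for i in range(n_mem_sas):
        accession = f"SAS{i:04d}"
        prevalence = (
            config.motif_prevalence_sensitive_sas
            if sensitivity[accession] == "sensitive"
            else config.motif_prevalence_resistant_sas
        )
        recs, truth = generate_sas(1, config, rng, motif_prevalence=prevalence, prefix=accession)
        rec = recs[0]
        rec = SignalSequenceRecord(
            accession=accession,
            full_sequence=rec.full_sequence,
            protein_class=rec.protein_class,
            signal_type=rec.signal_type,
            signal_start=rec.signal_start,
            signal_end=rec.signal_end,
            topology=rec.topology,
        )
        planted = truth[f"{accession}0000"]
        if planted is not None:
            planted = replace(planted, accession=accession)
        sequences.append(rec)
        motif_truth[accession] = planted

    unspec = generate_sp(n_mem_unspec, config, rng, ProteinClass.MEMBRANE, prefix="UNK")
    for rec in unspec:
        rec = SignalSequenceRecord(
            accession=rec.accession,
            full_sequence=rec.full_sequence,
            protein_class=rec.protein_class,
            signal_type=SignalType.UNSPECIFIED,
            signal_start=rec.signal_start,
            signal_end=rec.signal_end,
            topology=rec.topology,
        )
        sensitivity[rec.accession] = "sensitive" if rng.random() < p_mem else "resistant"
        motif_truth[rec.accession] = None
        sequences.append(rec)

    ratios: list[SilacRatioRecord] = []
    for rec in sequences:
        sensitive = sensitivity[rec.accession] == "sensitive"
        true_ratio = float(rng.uniform(*config.ratio_effect_range)) if sensitive else 1.0
        obs_f = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
        obs_r = true_ratio * float(_lognormal_noise(rng, config.ratio_noise_cv))
        ratios.append(
            SilacRatioRecord(
                accession=rec.accession,
                forward_ratio=obs_f,
                reverse_ratio=obs_r,
                protein_class=rec.protein_class,
                signal_type=rec.signal_type,
            )
        )
    return StudyData(
        sequences=sequences,
        ratios=ratios,
        sensitivity_truth=sensitivity,
        motif_truth=motif_truth,
        config=config,
    )
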
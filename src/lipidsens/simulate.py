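"""Synthetic lipid panels and LC-MS response tables.

Every stage of the pipeline is testable without instrument data: this module
builds chemically valid lipid panels (programmatic SMILES for ester-linked
glycerophospholipid, glycerolipid and ceramide scaffolds), draws a ground
truth sensitivity law in which log relative sensitivity is a smooth function
of molecular descriptors with class-level structure and within-class spread,
and renders noisy peak-area tables: linear response plus a blank background,
multiplicative lognormal noise, per-lipid matrix-effect factors, and optional
saturating responders whose top calibrator leaves the linear range.

The default panel mirrors the study conditions the pipeline assumes: 69
lipids across two ion modes, a six-level calibrant ladder with the 1:500 ..
1:10 dilution spacing (top:bottom concentration ratio 50), five replicate
study samples, 5 % multiplicative area noise and a blank at 5 % of the lowest
calibrant signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ResponseTable
from .descriptors import DescriptorMatrix, LipidRecord, clean_descriptors, compute_descriptors

#: 1:500 .. 1:10 dilution ladder; level-ℓ concentration = base * factor_ℓ/factor_1
DILUTION_FACTORS = (1 / 500, 1 / 200, 1 / 67, 1 / 33, 1 / 17, 1 / 10)

_CHOLESTEROL = "CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C"


def _tail(n_carbons: int, n_double_bonds: int) -> str:
    """Linear hydrocarbon tail SMILES with spaced cis-free double bonds."""
    if n_carbons < 1:
        raise ValueError("tail needs at least one carbon")
    if n_double_bonds < 0 or (n_double_bonds and 2 + 3 * (n_double_bonds - 1) >= n_carbons - 1):
        raise ValueError(
            f"cannot place {n_double_bonds} double bonds in a {n_carbons}-carbon tail"
        )
    dbl = {2 + 3 * i for i in range(n_double_bonds)}
    out = "C"
    for j in range(1, n_carbons):
        out += ("=" if (j - 1) in dbl else "") + "C"
    return out


def acyl_left(carbons: int, double_bonds: int) -> str:
    """Acyl group written tail-first, ending in the carbonyl: ``CCC...C(=O)``."""
    return _tail(carbons - 1, double_bonds) + "C(=O)"


def acyl_right(carbons: int, double_bonds: int) -> str:
    """Acyl group written carbonyl-first: ``C(=O)CCC...``."""
    return "C(=O)" + _tail(carbons - 1, double_bonds)


def build_smiles(lipid_class: str, chains: list[tuple[int, int]]) -> str:
    """SMILES for one lipid of a supported class given its acyl chains."""
    if lipid_class == "PC":
        a1, a2 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})COP(=O)([O-])OCC[N+](C)(C)C"
    if lipid_class == "PG":
        a1, a2 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})COP(=O)(O)OCC(O)CO"
    if lipid_class == "PI":
        a1, a2 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})COP(=O)(O)OC1C(O)C(O)C(O)C(O)C1O"
    if lipid_class == "PE":
        a1, a2 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})COP(=O)(O)OCCN"
    if lipid_class == "TG":
        a1, a2, a3 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})CO{acyl_right(*a3)}"
    if lipid_class == "DG":
        a1, a2 = chains
        return f"{acyl_left(*a1)}OCC(O{acyl_right(*a2)})CO"
    if lipid_class == "MG":
        (a1,) = chains
        return f"{acyl_left(*a1)}OCC(O)CO"
    if lipid_class == "LPC":
        (a1,) = chains
        return f"{acyl_left(*a1)}OCC(O)COP(=O)([O-])OCC[N+](C)(C)C"
    if lipid_class == "Cer":
        (amide,) = chains
        return f"CCCCCCCCCCCCCC=CC(O)C(CO){'N' + acyl_right(*amide)}"
    raise ValueError(f"unsupported lipid class {lipid_class!r}")


def shorthand_name(lipid_class: str, chains: list[tuple[int, int]]) -> str:
    if lipid_class == "Cer":
        (amide,) = chains
        return f"Cer d18:1/{amide[0]}:{amide[1]}"
    return f"{lipid_class} " + "-".join(f"{c}:{d}" for c, d in chains)


@dataclass
class ClassSpec:
    """Composition range of one simulated lipid class."""

    name: str
    ion_mode: str
    n_lipids: int
    n_chains: int
    chain_carbons: tuple[int, int] = (12, 22)  # inclusive per-chain range
    chain_double_bonds: tuple[int, int] = (0, 3)


def default_class_specs() -> list[ClassSpec]:
    """69-lipid two-mode panel (references included) used as the study default."""
    return [
        ClassSpec("PC", "positive", 12, 2),
        ClassSpec("TG", "positive", 12, 3, chain_carbons=(10, 22)),
        ClassSpec("DG", "positive", 8, 2),
        ClassSpec("LPC", "positive", 5, 1, chain_carbons=(12, 22)),
        ClassSpec("PG", "negative", 11, 2),
        ClassSpec("PI", "negative", 10, 2),
        ClassSpec("Cer", "negative", 9, 1, chain_carbons=(14, 26)),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the assumed study conditions."""

    class_specs: list[ClassSpec] = field(default_factory=default_class_specs)
    n_levels: int = 6
    dilution_factors: tuple = DILUTION_FACTORS
    n_replicate_samples: int = 5
    n_blanks: int = 3
    n_neat_spike_samples: int = 0
    study_level: int = 3

    # sensitivity law: log m_R = sum(w_k * z_k) + class offset + N(0, spread)
    informative_descriptors: list[str] | None = None  # None -> random choice
    informative_weights: list[float] | None = None    # None -> random weights
    n_informative: int = 5
    weight_scale: float = 0.8        # sd of the descriptor-driven log m_R term
    class_offset_sd: float = 0.7     # between-class log-sensitivity spread
    within_class_sd: float = 0.1     # unexplained within-class log spread
    within_class_sd_by_class: dict = field(default_factory=dict)
    out_of_law_class: str | None = None
    out_of_law_offset: float = 2.5   # log-scale shift of the out-of-law class

    # response model
    noise_sd: float = 0.05           # lognormal sigma of multiplicative noise
    blank_fraction: float = 0.05     # blank signal / lowest calibrant signal
    matrix_effect_sd: float = 0.0    # lognormal sigma of per-lipid matrix factors
    reference_gain: float = 1.0e5    # reference slope, area units per conc unit
    saturating_lipid_ids: list[str] = field(default_factory=list)
    saturation_cap: float = 0.6      # top-level area as fraction of level L-1 response

    seed: int = 0


def _level_concs(base: float, cfg: SimulationConfig) -> dict[int, float]:
    f0 = cfg.dilution_factors[0]
    return {
        lv + 1: base * cfg.dilution_factors[lv] / f0 for lv in range(cfg.n_levels)
    }


def generate_panel(cfg: SimulationConfig) -> list[LipidRecord]:
    """Deterministic panel of valid lipids plus one reference standard per mode."""
    rng = np.random.default_rng(cfg.seed)
    records: list[LipidRecord] = []
    for spec in cfg.class_specs:
        lo_c, hi_c = spec.chain_carbons
        lo_d, hi_d = spec.chain_double_bonds
        # enumerate feasible per-chain compositions once, then sample whole
        # lipids without repeating a composition within the class
        per_chain = [
            (c, d)
            for c in range(lo_c, hi_c + 1)
            for d in range(lo_d, hi_d + 1)
            if d == 0 or 2 + 3 * (d - 1) < c - 2
        ]
        if not per_chain:
            raise ValueError(f"class {spec.name}: chain ranges admit no valid composition")
        seen: set[tuple] = set()
        attempts = 0
        while len(seen) < spec.n_lipids:
            attempts += 1
            if attempts > 200 * spec.n_lipids:
                raise ValueError(f"class {spec.name}: cannot draw {spec.n_lipids} unique lipids")
            chains = tuple(
                sorted(per_chain[rng.integers(len(per_chain))] for _ in range(spec.n_chains))
            )
            seen.add(chains)
        for chains in sorted(seen):
            chains = list(chains)
            name = shorthand_name(spec.name, chains)
            base = float(np.exp(rng.normal(0.0, 0.3)))
            records.append(
                LipidRecord(
                    lipid_id=name.replace(" ", "_").replace("/", "_"),
                    name=name,
                    lipid_class=spec.name,
                    smiles=build_smiles(spec.name, chains),
                    ion_mode=spec.ion_mode,
                    spiked_conc=_level_concs(base, cfg),
                )
            )
    modes = {s.ion_mode for s in cfg.class_specs}
    if "positive" in modes:
        records.append(
            LipidRecord(
                lipid_id="cholesterol_d7",
                name="cholesterol-d7",
                lipid_class="ST",
                smiles=_CHOLESTEROL,
                ion_mode="positive",
                spiked_conc=_level_concs(1.0, cfg),
                is_reference_standard=True,
            )
        )
    if "negative" in modes:
        records.append(
            LipidRecord(
                lipid_id="MG_17_0_d7",
                name="MG-d7 17:0",
                lipid_class="MG",
                smiles=build_smiles("MG", [(17, 0)]),
                ion_mode="negative",
                spiked_conc=_level_concs(1.0, cfg),
                is_reference_standard=True,
            )
        )
    return records


def generate_ground_truth_mR(
    panel: list[LipidRecord],
    descriptors: DescriptorMatrix,
    cfg: SimulationConfig,
) -> pd.Series:
    """True relative sensitivities from the configured descriptor law.

    log m_R = weighted sum of standardized informative descriptors + class
    offset + within-class Normal spread; each mode's reference standard is
    forced to exactly 1 by renormalizing its mode.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    data = descriptors.data
    if cfg.informative_descriptors is not None:
        chosen = list(cfg.informative_descriptors)
        missing = [c for c in chosen if c not in data.columns]
        if missing:
            raise ValueError(f"informative descriptors not in matrix: {missing}")
    else:
        chosen = list(rng.choice(data.columns, size=cfg.n_informative, replace=False))
    Z = data[chosen].to_numpy(float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    if cfg.informative_weights is not None:
        if len(cfg.informative_weights) != len(chosen):
            raise ValueError("informative_weights length must match informative descriptors")
        w = np.asarray(cfg.informative_weights, float)
    else:
        w = rng.normal(0.0, 1.0, len(chosen))
    contrib = Z @ w
    sd = contrib.std()
    if sd > 0:
        contrib *= cfg.weight_scale / sd
    by_id = dict(zip(data.index, contrib))

    classes = sorted({r.lipid_class for r in panel})
    offsets = {
        cls: (0.0 if cfg.class_offset_sd == 0 else float(rng.normal(0.0, cfg.class_offset_sd)))
        for cls in classes
    }
    log_mR = {}
    for rec in panel:
        if rec.lipid_id not in by_id:
            continue
        spread = cfg.within_class_sd_by_class.get(rec.lipid_class, cfg.within_class_sd)
        val = by_id[rec.lipid_id] + offsets[rec.lipid_class]
        if spread > 0:
            val += float(rng.normal(0.0, spread))
        if cfg.out_of_law_class is not None and rec.lipid_class == cfg.out_of_law_class:
            val += cfg.out_of_law_offset
        log_mR[rec.lipid_id] = val
    mR = pd.Series({k: float(np.exp(v)) for k, v in log_mR.items()}, name="true_mR")
    for mode in ("positive", "negative"):
        ref = next(
            (r for r in panel if r.ion_mode == mode and r.is_reference_standard), None
        )
        if ref is None or ref.lipid_id not in mR.index:
            continue
        mode_ids = [r.lipid_id for r in panel if r.ion_mode == mode and r.lipid_id in mR.index]
        mR.loc[mode_ids] = mR.loc[mode_ids] / mR.loc[ref.lipid_id]
    return mR


def generate_responses(
    panel: list[LipidRecord],
    true_mR: pd.Series,
    cfg: SimulationConfig,
) -> tuple[ResponseTable, pd.Series, dict[str, float]]:
    """Noisy peak-area tables for calibrants, study replicates, blanks, neat spikes.

    Returns (responses, true study-sample concentration per lipid, per-lipid
    matrix-effect factor).  area = m·conc + blank, all times lognormal noise
    and the lipid's matrix factor (reference factor fixed at 1); blanks carry
    only background; a saturating lipid's top calibrator is capped at
    ``saturation_cap`` times its level-(L-1) linear response.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    by_id = {r.lipid_id: r for r in panel}
    slopes = {lid: cfg.reference_gain * float(true_mR.loc[lid]) for lid in true_mR.index}
    blanks = {
        lid: cfg.blank_fraction * slopes[lid] * by_id[lid].spiked_conc[1]
        for lid in slopes
    }
    matrix = {}
    for lid in slopes:
        if by_id[lid].is_reference_standard or cfg.matrix_effect_sd == 0:
            matrix[lid] = 1.0
        else:
            matrix[lid] = float(np.exp(rng.normal(0.0, cfg.matrix_effect_sd)))

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, cfg.noise_sd))) if cfg.noise_sd > 0 else 1.0

    meta_rows, area_rows = [], {}
    for mode in ("positive", "negative"):
        mode_ids = [r.lipid_id for r in panel if r.ion_mode == mode and r.lipid_id in slopes]
        if not mode_ids:
            continue
        tag = "pos" if mode == "positive" else "neg"

        def emit(sample_id: str, role: str, level, areas: dict) -> None:
            meta_rows.append(
                {
                    "sample_id": sample_id, "role": role, "calibration_level": level,
                    "donor": "donor1", "ion_mode": mode,
                }
            )
            area_rows[sample_id] = areas

        for lv in range(1, cfg.n_levels + 1):
            areas = {}
            for lid in mode_ids:
                conc = by_id[lid].spiked_conc[lv]
                signal = slopes[lid] * conc + blanks[lid]
                if lid in cfg.saturating_lipid_ids and lv == cfg.n_levels:
                    prev = by_id[lid].spiked_conc[cfg.n_levels - 1]
                    signal = cfg.saturation_cap * (slopes[lid] * prev + blanks[lid])
                areas[lid] = signal * matrix[lid] * noise()
            emit(f"{tag}_cal_{lv}", "calibrant", lv, areas)
        for rep in range(1, cfg.n_replicate_samples + 1):
            areas = {
                lid: (slopes[lid] * by_id[lid].spiked_conc[cfg.study_level] + blanks[lid])
                * matrix[lid] * noise()
                for lid in mode_ids
            }
            emit(f"{tag}_study_{rep}", "study_sample", None, areas)
        for rep in range(1, cfg.n_blanks + 1):
            emit(
                f"{tag}_blank_{rep}", "blank", None,
                {lid: blanks[lid] * noise() for lid in mode_ids},
            )
        for rep in range(1, cfg.n_neat_spike_samples + 1):
            areas = {
                lid: (slopes[lid] * by_id[lid].spiked_conc[cfg.study_level] + blanks[lid])
                * noise()
                for lid in mode_ids
            }
            emit(f"{tag}_neat_{rep}", "neat_spike", None, areas)

    samples = pd.DataFrame(meta_rows)
    areas_df = pd.DataFrame.from_dict(area_rows, orient="index")
    areas_df = areas_df.loc[samples["sample_id"]]
    true_conc = pd.Series(
        {lid: by_id[lid].spiked_conc[cfg.study_level] for lid in slopes}, name="true_conc"
    )
    return ResponseTable(samples=samples, areas=areas_df), true_conc, matrix


@dataclass
class SimulatedStudy:
    """One fully generated study: panel, descriptors, truth and responses."""

    cfg: SimulationConfig
    panel: list[LipidRecord]
    descriptors: DescriptorMatrix  # cleaned
    true_mR: pd.Series
    responses: ResponseTable
    true_conc: pd.Series
    matrix_factors: dict[str, float]

    def reference(self, mode: str) -> LipidRecord:
        return next(r for r in self.panel if r.ion_mode == mode and r.is_reference_standard)

    def class_labels(self) -> pd.Series:
        return pd.Series({r.lipid_id: r.lipid_class for r in self.panel})

    def masses(self) -> pd.Series:
        return pd.Series({r.lipid_id: r.monoisotopic_mass for r in self.panel})


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate panel, descriptors, ground truth and responses in one call."""
    panel = generate_panel(cfg)
    descriptors = clean_descriptors(compute_descriptors(panel))
    true_mR = generate_ground_truth_mR(panel, descriptors, cfg)
    responses, true_conc, matrix = generate_responses(panel, true_mR, cfg)
    return SimulatedStudy(cfg, panel, descriptors, true_mR, responses, true_conc, matrix)
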
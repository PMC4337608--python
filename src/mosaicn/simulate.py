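"""Forward simulators for every input table the pipeline consumes.

Each generator implements the statistical model the corresponding
analysis assumes, with a truth table alongside, so recovery can be tested
end to end without any measured data:

* Ct replicate tables — per-nucleus true copy number drawn from a
  group/region mixture; replicate Cts are a deterministic copy-number
  mean plus Gaussian noise with the system SD of 0.25 cycles, in the
  nominal 18-replicate design (3 sample loads x 6 assay replicates).
  All biological signal sits in the target-gene Ct; the reference gene
  and the paired cerebellar calibrator nuclei are fixed at two copies.
* standard curves — colinear dilution points from a known efficiency
  (slope = -1/log10(1+E)) plus optional Ct noise.
* flow-cytometry event tables — a G0/G1 Gaussian peak, an optional
  right-shifted shoulder subpopulation, uniform debris, a CEN
  calibration peak, and an optional bimodal NeuN channel.
* FISH count tables — multinomial spot-class draws per brain/observer.
* PNA intensity records — log-normal puncta intensities whose exceedance
  of the detection threshold is set per group, plus lipofuscin and
  telomere-failure contamination handled by the exclusion rules.

Default group mixtures are calibrated so cohort summaries land near the
published single-neuron profile (group means 3.80 / 2.23 / 1.60 / 2.28
and an AD-cortex >2-copy fraction near 60%) — an emulation of that
data's statistical structure, not a reproduction of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIXTURES",
    "DEFAULT_EFFICIENCIES",
    "SimulationConfig",
    "simulate_standard_curve",
    "simulate_ct_table",
    "simulate_flow_events",
    "simulate_fish_counts",
    "simulate_pna",
    "write_inputs",
]

# True copy-number mixtures per (group, region); chosen once so that the
# mixture means are 3.80 (AD CTX), 2.23 (AD CBL), 1.60 (ND CTX), 2.28
# (ND CBL) with a >2-copy mass of 0.58 / 0.22 / 0.12 / 0.22.
DEFAULT_MIXTURES: dict[tuple[str, str], dict[int, float]] = {
    ("AD", "CTX"): {1: 0.05, 2: 0.37, 3: 0.15, 4: 0.13, 5: 0.10, 6: 0.10,
                    8: 0.05, 10: 0.03, 12: 0.02},
    ("AD", "CBL"): {1: 0.08, 2: 0.70, 3: 0.15, 4: 0.05, 5: 0.02},
    ("ND", "CTX"): {1: 0.52, 2: 0.36, 3: 0.12},
    ("ND", "CBL"): {1: 0.05, 2: 0.73, 3: 0.13, 4: 0.07, 5: 0.02},
}

# Observed TaqMan assay efficiencies.
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "APP_ex3": 0.992,
    "APP_ex14": 1.040,
    "SEMA4A": 1.016,
    "PCDH11X": 0.993,
}


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the study-like conditions."""

    seed: int = 0
    # qPCR
    n_nuclei: int = 38                 # analyzed nuclei per group/region
    n_brains: int = 3                  # brains per group
    n_calibrators: int = 12            # CN-2 cerebellar calibrator nuclei per brain
    n_replicates: int = 18             # 3 sample loads x 6 assay replicates
    ct_noise_sd: float = 0.25          # system SD, cycles
    target_assay: str = "APP_ex3"
    reference_assay: str = "SEMA4A"
    efficiencies: dict = field(default_factory=lambda: dict(DEFAULT_EFFICIENCIES))
    mixtures: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MIXTURES.items()})
    base_ct_reference: float = 24.5    # mean reference-gene Ct, cycles
    base_ct_target: float = 21.0       # mean target Ct at two copies, cycles
    # flow cytometry
    flow_n_events: int = 10_000
    flow_reference_mode: float = 100.0  # reference 2N peak position, a.u.
    flow_peak_cv: float = 0.05          # within-peak CV of PI intensity
    flow_true_di: float = 1.08          # sample DI relative to reference
    flow_shoulder_fraction: float = 0.0
    flow_shoulder_shift: float = 0.20   # shoulder displacement, fraction of mode
    flow_cen_position: float = 0.35     # CEN peak, fraction of reference mode
    flow_cen_fraction: float = 0.15     # fraction of events that are CEN
    flow_debris_fraction: float = 0.02
    flow_neun_positive_fraction: float = 0.7
    # FISH
    fish_class_probs: tuple = (0.03, 0.92, 0.035, 0.015)  # mono/di/tri/tetrasomy
    fish_n_nuclei_per_brain: int = 500
    fish_n_brains: dict = field(default_factory=lambda: {"AD": 9, "ND": 5})
    fish_n_observers: int = 3
    # PNA
    pna_positive_fraction: dict = field(
        default_factory=lambda: {"AD": 0.56, "ND": 0.22, "DS": 0.14}
    )
    pna_n_nuclei: dict = field(default_factory=lambda: {"AD": 100, "ND": 100, "DS": 50})
    pna_threshold: float = 1.0          # detection threshold, relative intensity
    pna_lognorm_sigma: float = 0.4
    pna_lipofuscin_fraction: float = 0.05
    pna_telomere_failure_fraction: float = 0.02

    def validate(self) -> None:
        for key, mix in self.mixtures.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture for {key} sums to {total}, expected 1")
            if any(k < 1 for k in mix):
                raise ValueError(f"mixture for {key} has copy number < 1")
        if abs(sum(self.fish_class_probs) - 1.0) > 1e-9:
            raise ValueError("fish class probabilities must sum to 1")
        for n in (self.n_nuclei, self.n_brains, self.n_calibrators, self.n_replicates):
            if n < 1:
                raise ValueError("all design counts must be >= 1")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_standard_curve(
    efficiency: float,
    noise_sd: float = 0.0,
    levels=(1.0, 2.0, 3.0, 4.0, 5.0),
    intercept: float = 38.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dilution-series points with slope = -1/log10(1+E)."""
    rng = rng or np.random.default_rng(0)
    slope = -1.0 / np.log10(1.0 + efficiency)
    x = np.asarray(levels, dtype=float)
    ct = intercept + slope * x + rng.normal(0.0, noise_sd, x.size)
    return pd.DataFrame({"log10_copies": x, "ct": ct})


def _target_mean_ct(cn: float, efficiency: float, base_target: float) -> float:
    # One extra template doubling shifts Ct by -log_{1+E}(fold change).
    return base_target - np.log(cn / 2.0) / np.log(1.0 + efficiency)


def simulate_ct_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct replicate table plus truth table for the single-nucleus design.

    Every brain contributes ``n_calibrators`` cerebellar calibrator
    nuclei fixed at two copies, and each (group, region) mixture
    contributes ``n_nuclei`` analyzed nuclei spread round-robin over the
    group's brains. Replicate Cts are the deterministic copy-number mean
    plus N(0, ct_noise_sd) noise for both target and reference assays.

    Returns ``(ct_table, truth)``; truth columns include the true copy
    number and an ``is_calibrator`` flag.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    e_target = config.efficiencies[config.target_assay]

    ct_rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(unit: str, brain: str, region: str, group: str, cn: int,
             calibrator: bool) -> None:
        truth_rows.append({
            "unit_id": unit, "brain_id": brain, "region": region,
            "group": group, "true_cn": cn, "is_calibrator": calibrator,
        })
        tgt_mean = _target_mean_ct(cn, e_target, config.base_ct_target)
        for assay, mean in ((config.target_assay, tgt_mean),
                            (config.reference_assay, config.base_ct_reference)):
            noise = rng.normal(0.0, config.ct_noise_sd, config.n_replicates)
            for i, eps in enumerate(noise):
                ct_rows.append({
                    "unit_id": unit, "brain_id": brain, "region": region,
                    "group": group, "assay_id": assay,
                    "replicate_index": i, "ct": mean + eps,
                })

    groups = sorted({g for g, _ in config.mixtures})
    for group in groups:
        brains = [f"{group}-{b + 1}" for b in range(config.n_brains)]
        for brain in brains:
            for j in range(config.n_calibrators):
                emit(f"{brain}_CBLcal{j:02d}", brain, "CBL", group, 2, True)
        for (g, region), mix in sorted(config.mixtures.items()):
            if g != group:
                continue
            cns = np.array(sorted(mix), dtype=int)
            probs = np.array([mix[int(k)] for k in cns], dtype=float)
            draws = rng.choice(cns, size=config.n_nuclei, p=probs)
            for j, cn in enumerate(draws):
                brain = brains[j % len(brains)]
                emit(f"{brain}_{region}{j:03d}", brain, region, group, int(cn), False)

    ct_table = pd.DataFrame(ct_rows)
    truth = pd.DataFrame(truth_rows)
    return ct_table, truth


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

def simulate_flow_events(
    config: SimulationConfig,
    sample_id: str = "S1",
    true_di: float | None = None,
    shoulder_fraction: float | None = None,
    with_neun: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Event table for one tube: 2N peak, optional shoulder, CEN, debris.

    ``true_di`` scales the sample's main peak relative to the reference
    mode; the CEN peak stays put, so the configured DI is exactly what
    the DI computation should recover against a ``true_di = 1`` reference
    tube.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    di = config.flow_true_di if true_di is None else true_di
    sh_frac = config.flow_shoulder_fraction if shoulder_fraction is None else shoulder_fraction

    n = config.flow_n_events
    n_cen = int(round(n * config.flow_cen_fraction))
    n_debris = int(round(n * config.flow_debris_fraction))
    n_main_total = n - n_cen - n_debris
    n_shoulder = int(round(n_main_total * sh_frac))
    n_main = n_main_total - n_shoulder

    mode = config.flow_reference_mode * di
    sd = config.flow_peak_cv * mode
    main = rng.normal(mode, sd, n_main)
    shoulder = rng.normal(mode * (1.0 + config.flow_shoulder_shift), sd, n_shoulder)
    cen_mode = config.flow_cen_position * config.flow_reference_mode
    cen = rng.normal(cen_mode, config.flow_peak_cv * cen_mode, n_cen)
    debris = rng.uniform(cen_mode * 1.6, mode * 0.9, n_debris)

    pi = np.concatenate([main, shoulder, debris, cen])
    tag = np.array(["sample"] * (n_main + n_shoulder + n_debris) + ["CEN"] * n_cen)
    fsc = rng.normal(100.0, 8.0, pi.size)
    df = pd.DataFrame({
        "sample_id": sample_id,
        "event_id": np.arange(pi.size),
        "pi_intensity": np.clip(pi, 0.0, None),
        "fsc_w": fsc,
        "species_tag": tag,
    })
    if with_neun:
        is_sample = tag == "sample"
        pos = rng.random(pi.size) < config.flow_neun_positive_fraction
        neun = np.where(pos & is_sample,
                        rng.normal(1000.0, 150.0, pi.size),
                        rng.normal(50.0, 15.0, pi.size))
        df["neun_intensity"] = np.clip(neun, 0.0, None)
        df["neun_true_positive"] = pos & is_sample
    return df


# ---------------------------------------------------------------------------
# FISH and PNA
# ---------------------------------------------------------------------------

def simulate_fish_counts(
    config: SimulationConfig,
    class_probs_by_group: dict[str, tuple] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial aneusomy-class counts per brain and observer."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for group, n_brains in sorted(config.fish_n_brains.items()):
        probs = np.asarray(
            (class_probs_by_group or {}).get(group, config.fish_class_probs),
            dtype=float,
        )
        for b in range(n_brains):
            for obs in range(config.fish_n_observers):
                counts = rng.multinomial(config.fish_n_nuclei_per_brain, probs)
                rows.append({
                    "brain_id": f"{group}-{b + 1}", "group": group,
                    "observer_id": f"obs{obs + 1}",
                    "monosomy": int(counts[0]), "disomy": int(counts[1]),
                    "trisomy": int(counts[2]), "tetrasomy": int(counts[3]),
                    "n_nuclei": int(counts.sum()),
                })
    return pd.DataFrame(rows)


def simulate_pna(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-nucleus puncta intensity records with exclusion contaminants.

    Positive nuclei draw log-normal intensities above the detection
    threshold, negative nuclei below it; a lipofuscin punctum (bright in
    all channels) is added to a small fraction of nuclei, and a small
    fraction lacks the telomere control signal. Negative-control records
    (ND-group blanks) set the "auto" threshold just under the configured
    one. A ``true_positive`` column carries generator truth.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    thr = config.pna_threshold
    sigma = config.pna_lognorm_sigma
    rows = []
    for group, n in sorted(config.pna_n_nuclei.items()):
        p_pos = config.pna_positive_fraction[group]
        positive = rng.random(n) < p_pos
        for j in range(n):
            unit = f"{group}_n{j:03d}"
            telomere_ok = rng.random() >= config.pna_telomere_failure_fraction
            if positive[j]:
                intensity = thr * float(np.exp(rng.normal(0.5 * sigma + 0.2, sigma)))
                intensity = max(intensity, thr)
                n_puncta = 2 if rng.random() < 0.1 else 1
            else:
                intensity = thr * float(np.exp(rng.normal(-1.5, sigma)))
                intensity = min(intensity, thr * 0.999)
                n_puncta = 1 if rng.random() < 0.3 else 0
            rows.append({
                "unit_id": unit, "group": group, "intensity": intensity,
                "n_puncta": n_puncta, "lipofuscin": False,
                "telomere_present": telomere_ok, "is_negative_control": False,
                "true_positive": bool(positive[j] and telomere_ok),
            })
            if rng.random() < config.pna_lipofuscin_fraction:
                rows.append({
                    "unit_id": unit, "group": group,
                    "intensity": thr * float(np.exp(rng.normal(1.0, sigma))),
                    "n_puncta": n_puncta, "lipofuscin": True,
                    "telomere_present": telomere_ok,
                    "is_negative_control": False,
                    "true_positive": bool(positive[j] and telomere_ok),
                })
    # blank negative controls pin the auto threshold just below `thr`
    for j in range(30):
        rows.append({
            "unit_id": f"NC_n{j:03d}", "group": "NC",
            "intensity": thr * 0.999 * float(np.exp(-np.abs(rng.normal(0.3, 0.2)))),
            "n_puncta": 0, "lipofuscin": False, "telomere_present": True,
            "is_negative_control": True, "true_positive": False,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled output
# ---------------------------------------------------------------------------

def write_inputs(config: SimulationConfig, out_dir: str | Path) -> list[Path]:
    """Write every pipeline input CSV (plus truth tables) to a directory.

    Deterministic: the same config (including seed) produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    curves = []
    for assay, eff in sorted(config.efficiencies.items()):
        pts = simulate_standard_curve(eff, noise_sd=0.05, rng=rng)
        pts.insert(0, "assay_id", assay)
        curves.append(pts)
    save(pd.concat(curves, ignore_index=True), "standard_curve.csv")

    ct, truth = simulate_ct_table(config, rng=rng)
    save(ct, "ct_replicates.csv")
    save(truth, "truth_ct.csv")

    tubes = [simulate_flow_events(config, "LYM-ref", true_di=1.0, rng=rng)]
    tubes.append(simulate_flow_events(config, "AD-CTX-1",
                                      true_di=config.flow_true_di,
                                      shoulder_fraction=0.2, rng=rng))
    tubes.append(simulate_flow_events(config, "AD-CBL-1", true_di=1.0, rng=rng))
    save(pd.concat(tubes, ignore_index=True), "events.csv")

    save(simulate_fish_counts(config, rng=rng), "fish_counts.csv")
    save(simulate_pna(config, rng=rng), "pna_intensities.csv")
    return written
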
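"""Synthetic-data generators with ground-truth tables.

Every input the pipeline consumes can be generated here with its truth
recorded, so downstream calls can be asserted exactly:

* ortholog sequences with programmed Q1/Q2 runs, proline interruptions,
  a single embedded histidine, hinge variants and an optional hinge
  extension (e.g. the 22-residue cetacean-style insertion);
* species panels whose log10 vocalization frequency and log10 body mass
  depend linearly (plus Gaussian noise) on the Q1/Q2 ratio;
* FRAP traces following the single-exponential recovery model, with
  optional acquisition photobleaching shared with control regions;
* two-state CD spectra mixing two fixed synthetic basis curves that share
  an isodichroic crossing at 203 nm (documented shapes, no claim of
  physical realism);
* two-channel luminescence plates with per-group firefly/Renilla effects.

Flanking sequence is drawn from an alphabet excluding Q, P and H so that
programmed runs stay unambiguous.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assays import CDSpectrum, FRAPTrace
from .io import OrthologRecord, write_fasta
from .repeats import ANCHORS, HingeConfig

#: flank alphabet: the 20 canonical residues minus Q, P, H
FLANK_ALPHABET = "ACDEFGIKLMNRSTVWY"

#: the hinge-extension insertion peptide reported for Tursiops truncatus
CETACEAN_EXTENSION = "VGSGRLTHAEEGEAGRGPRRPG"


# --------------------------------------------------------------------------
# ortholog sequences
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologSpec:
    """Programmed repeat architecture for one synthetic ortholog.

    ``proline_fragments`` lists the lengths of fragmented Q-runs inserted
    between the Q1 run and the hinge, each preceded by a proline; the
    repeat caller must ignore them.  ``histidine_in_q1`` embeds one H at an
    interior position of the Q1 run (counting toward its length).
    """

    q1: int
    q2: int
    proline_fragments: tuple[int, ...] = ()
    histidine_in_q1: bool = False
    hinge_variant: Optional[str] = None
    extension_peptide: Optional[str] = None
    flank_lengths: tuple[int, int] = (30, 60)
    seed: int = 0

    def validate(self, cfg: HingeConfig) -> None:
        if self.q1 < cfg.min_run or self.q2 < cfg.min_run:
            raise ValueError(f"q1 and q2 must be >= min_run ({cfg.min_run})")
        if self.histidine_in_q1 and self.q1 < 3:
            raise ValueError("an interior histidine requires q1 >= 3")
        if any(f < 1 for f in self.proline_fragments):
            raise ValueError("proline fragments must have length >= 1")
        upstream = self.q1 + sum(1 + f for f in self.proline_fragments)
        if upstream > cfg.upstream_window:
            raise ValueError(
                f"programmed upstream region ({upstream}) exceeds the "
                f"upstream window ({cfg.upstream_window})"
            )
        ext = self.extension_peptide or ""
        if "Q" in ext:
            raise ValueError("extension peptide must not contain Q")
        if len(ext) > cfg.downstream_window:
            raise ValueError("extension exceeds the downstream window")


def gen_ortholog(
    spec: OrthologSpec,
    gene: str = "FOXP2",
    cfg: Optional[HingeConfig] = None,
    species_label: Optional[str] = None,
    sequence_id: Optional[str] = None,
) -> tuple[OrthologRecord, dict]:
    """Build one synthetic ortholog plus its truth record.

    Layout: M + flank + Q1 run (optional interior H) + per-fragment
    (P + Q-run) + hinge + optional extension + Q2 run + flank.
    """
    cfg = cfg or HingeConfig(gene=gene)
    spec.validate(cfg)
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(FLANK_ALPHABET))

    def flank(n: int) -> str:
        return "".join(rng.choice(alphabet, size=n))

    if spec.histidine_in_q1:
        h_at = spec.q1 // 2
        q1_block = "Q" * h_at + "H" + "Q" * (spec.q1 - h_at - 1)
    else:
        q1_block = "Q" * spec.q1
    fragments = "".join("P" + "Q" * f for f in spec.proline_fragments)
    hinge = spec.hinge_variant or ANCHORS[gene]
    ext = spec.extension_peptide or ""
    seq = (
        "M"
        + flank(spec.flank_lengths[0])
        + q1_block
        + fragments
        + hinge
        + ext
        + "Q" * spec.q2
        + flank(spec.flank_lengths[1])
    )
    record = OrthologRecord(
        species_label=species_label or f"synthetic_sp{spec.seed}",
        gene=gene,
        sequence_id=sequence_id or f"SYN{spec.seed}",
        sequence=seq,
        taxon="synthetic",
    )
    truth = {
        "q1": spec.q1,
        "q2": spec.q2,
        "sum": spec.q1 + spec.q2,
        "ratio": spec.q1 / spec.q2,
        "extension_len": len(ext) if len(ext) > cfg.context_allowance else 0,
        "q1_contains_histidine": spec.histidine_in_q1,
        "q1_truncated_by_proline": bool(spec.proline_fragments),
    }
    return record, truth


# --------------------------------------------------------------------------
# species panels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelModel:
    """Linear ratio -> log-phenotype model behind a synthetic species panel.

    log10(frequency kHz) = intercept_logfreq + slope * ratio + N(0, noise);
    log10(body mass g) is analogous with its own slope and intercept.
    Ratios are drawn uniformly over ``ratio_range`` and quantized to an
    integer (q1, q2) pair with q2 in [2, 20].
    """

    n_species: int = 200
    ratio_range: tuple[float, float] = (0.5, 5.5)
    slope_logfreq_per_ratio: float = -0.35
    intercept_logfreq: float = 2.0
    noise_sd: float = 0.15
    slope_logmass_per_ratio: float = 0.8
    intercept_logmass: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ratio_range[0] >= self.ratio_range[1]:
            raise ValueError("ratio_range must be (low, high) with low < high")


def quantize_ratio(
    ratio: float, q2_max: int = 20, q1_max: int = 95, min_run: int = 2
) -> tuple[int, int]:
    """Integer (q1, q2) minimizing |q1/q2 - ratio|, smallest q2 on ties."""
    best = None
    for q2 in range(min_run, q2_max + 1):
        q1 = int(np.clip(round(ratio * q2), min_run, q1_max))
        err = abs(q1 / q2 - ratio)
        if best is None or err < best[0] - 1e-12:
            best = (err, q1, q2)
    return best[1], best[2]


@dataclass(frozen=True)
class PanelData:
    fasta_text: str
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


def gen_panel_with_phenotypes(model: PanelModel = PanelModel()) -> PanelData:
    """Generate a species panel: FASTA + phenotype table + truth table."""
    rng = np.random.default_rng(model.seed)
    ratios = rng.uniform(*model.ratio_range, size=model.n_species)
    rows = []
    records = []
    for i, ratio in enumerate(ratios):
        q1, q2 = quantize_ratio(ratio)
        logf = (
            model.intercept_logfreq
            + model.slope_logfreq_per_ratio * ratio
            + rng.normal(0.0, model.noise_sd)
        )
        logm = (
            model.intercept_logmass
            + model.slope_logmass_per_ratio * ratio
            + rng.normal(0.0, model.noise_sd)
        )
        species = f"sp{i:04d}"
        record, _ = gen_ortholog(
            OrthologSpec(q1=q1, q2=q2, seed=int(rng.integers(0, 2**31 - 1))),
            species_label=species,
            sequence_id=f"SYN{i:04d}",
        )
        records.append(record)
        rows.append(
            {
                "species": species,
                "ratio_target": ratio,
                "q1": q1,
                "q2": q2,
                "ratio_quantized": q1 / q2,
                "log10_freq": logf,
                "log10_mass": logm,
            }
        )
    truth = pd.DataFrame(rows)
    phenotypes = pd.DataFrame(
        {
            "species": truth["species"],
            "min_freq_khz": 10.0 ** truth["log10_freq"],
            "body_mass_g": 10.0 ** truth["log10_mass"],
        }
    )
    return PanelData(write_fasta(records), phenotypes, truth)


def expected_group_correlation(
    model: PanelModel,
    edges: Sequence[float],
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Brute-force Monte-Carlo estimate of the model's group-level Pearson r.

    Simulates the model directly in numpy (drawn ratio -> quantized ratio,
    log10 frequency with noise), bins the quantized ratio on ``edges`` with
    the first bin closed at its upper edge, and correlates per-bin means.
    Serves as the independent target for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    ratios = rng.uniform(*model.ratio_range, size=n_mc)
    quantized = np.array([q1 / q2 for q1, q2 in (quantize_ratio(r) for r in ratios)])
    logf = (
        model.intercept_logfreq
        + model.slope_logfreq_per_ratio * ratios
        + rng.normal(0.0, model.noise_sd, size=n_mc)
    )
    bins = np.searchsorted(np.asarray(edges, dtype=float), quantized, side="left")
    mx, my = [], []
    for b in np.unique(bins):
        mask = bins == b
        mx.append(quantized[mask].mean())
        my.append(logf[mask].mean())
    return float(np.corrcoef(mx, my)[0, 1])


# --------------------------------------------------------------------------
# assay fixtures
# --------------------------------------------------------------------------

def gen_frap_trace(
    tau_s: float = 24.28,
    f0: float = 0.1,
    plateau: float = 0.802,
    noise_sd: float = 0.0,
    n_prebleach: int = 3,
    n_post: int = 120,
    dt_s: float = 1.0,
    shared_decay_rate: float = 0.0,
    base_intensity: float = 100.0,
    n_controls: int = 2,
    seed: int = 0,
) -> tuple[FRAPTrace, dict]:
    """Single-exponential recovery trace plus truth parameters.

    ``shared_decay_rate`` applies a common exponential acquisition-bleaching
    drift to both the bleached and control series, which the double
    normalization must cancel.  Noise is multiplicative Gaussian.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_prebleach + n_post
    time = np.arange(n) * dt_s
    t_post = time[n_prebleach:] - time[n_prebleach]
    ideal = np.ones(n)
    ideal[n_prebleach:] = f0 + (plateau - f0) * (1.0 - np.exp(-t_post / tau_s))
    decay = np.exp(-shared_decay_rate * time)

    def noisy(base: np.ndarray) -> np.ndarray:
        return base * (1.0 + rng.normal(0.0, noise_sd, size=n))

    bleached = noisy(base_intensity * ideal * decay)
    controls = np.stack(
        [noisy(base_intensity * rng.uniform(0.8, 1.2) * decay) for _ in range(n_controls)]
    )
    trace = FRAPTrace(time, bleached, controls, n_prebleach=n_prebleach)
    truth = {
        "tau_s": tau_s,
        "t_half_s": tau_s * np.log(2),
        "f0": f0,
        "plateau": plateau,
        "mobile_fraction": (plateau - f0) / (1.0 - f0),
    }
    return trace, truth


def _gauss(wl: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-((wl - mu) ** 2) / (2.0 * sd**2))


def cd_basis_coil(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Synthetic 'disordered' basis curve (units: deg cm2 dmol-1)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 1000.0 * (-18.0 * _gauss(wl, 198, 7) + 2.0 * _gauss(wl, 218, 15))


def cd_basis_helix(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Synthetic 'structured' basis curve sharing the coil value at 203 nm.

    Built as coil + a difference shape pinned to zero at 203 nm, so every
    mixture of the two bases passes through the same point at 203 nm (an
    exact isodichroic crossing).  Documented synthetic shapes only.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)

    def delta(x):
        return 1000.0 * (
            -9.0 * _gauss(x, 222, 9) - 6.0 * _gauss(x, 209, 5) + 45.0 * _gauss(x, 193, 5.5)
        )

    d203 = delta(np.array([203.0]))[0]
    return cd_basis_coil(wl) + delta(wl) - d203 * _gauss(wl, 203, 15)


def gen_cd_spectra(
    temperatures_c: Sequence[float] = (5, 25, 50, 75),
    weights: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    wavelengths_nm: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[list[CDSpectrum], dict]:
    """Two-state temperature series: weight*helix + (1-weight)*coil.

    Default weights decrease linearly with temperature (structure melts).
    Spectra carry the synthetic values directly as MRE.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wl = (
        np.arange(190.0, 261.0, 1.0)
        if wavelengths_nm is None
        else np.asarray(wavelengths_nm, dtype=float)
    )
    temps = np.asarray(temperatures_c, dtype=float)
    if weights is None:
        weights = 1.0 - (temps - temps.min()) / (temps.max() - temps.min() + 1e-12) * 0.8
    weights = np.asarray(weights, dtype=float)
    helix, coil = cd_basis_helix(wl), cd_basis_coil(wl)
    spectra = []
    for t, w in zip(temps, weights):
        values = w * helix + (1.0 - w) * coil + rng.normal(0.0, noise_sd, size=len(wl))
        spectra.append(CDSpectrum(wl, values, float(t), mre=values))
    truth = {
        "weights": dict(zip(map(float, temps), map(float, weights))),
        "basis_difference": helix - coil,
        "isodichroic_nm": 203.0,
    }
    return spectra, truth


def gen_luciferase_plate(
    group_effects: Optional[dict[str, float]] = None,
    wells_per_group: int = 12,
    renilla_mean: float = 1e5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-channel plate: firefly = effect * Renilla * noise.

    ``group_effects`` maps group label to the programmed normalized
    luminescence (the control group should have effect 1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if group_effects is None:
        group_effects = {"control": 1.0, "treated": 0.79}
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for group, effect in group_effects.items():
        for _ in range(wells_per_group):
            renilla = renilla_mean * rng.lognormal(0.0, 0.1)
            firefly = effect * renilla * np.exp(rng.normal(0.0, noise_sd))
            rows.append(
                {"well": well, "group": group, "firefly": firefly, "renilla": renilla}
            )
            well += 1
    return pd.DataFrame(rows), {"group_effects": dict(group_effects)}


def gen_assay_fixtures(kind: str, params: Optional[dict] = None, seed: int = 0):
    """Dispatch to the FRAP / CD / LUC generator by kind."""
    params = dict(params or {})
    params["seed"] = seed
    if kind.upper() == "FRAP":
        return gen_frap_trace(**params)
    if kind.upper() == "CD":
        return gen_cd_spectra(**params)
    if kind.upper() == "LUC":
        return gen_luciferase_plate(**params)
    raise ValueError(f"unknown assay fixture kind {kind!r}")
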
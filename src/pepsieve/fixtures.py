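"""Synthetic fixtures with known ground truth for every pipeline stage.

Real endogenous-peptidomics raw data (multi-run timsTOF acquisitions plus
specific proteome releases) is far too large to regenerate at desk scale, so
each generator here emulates the *structure* the pipeline consumes and emits
machine-readable ground truth alongside:

* Venn-structured proteome sets with exact planted cell counts;
* sORF predictions with planted stop-sharing groups and single-exon
  coding-overlap decoys, plus the exact expected survivor list;
* b/y spectra whose predicted-vs-observed intensity correlation is tunable;
* two-Gaussian target/decoy PSM score mixtures with per-PSM correctness
  labels for FDR-calibration experiments.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fasta_db import ExonInterval, Locus, SeqRecord, Source
from .rescore import transform_intensities
from .spectra import (
    PROTON_MASS,
    Peptidoform,
    Spectrum,
    fragment_mz,
    monoisotopic_mass,
)

__all__ = [
    "SpectraConfig",
    "PsmMixtureConfig",
    "SimConfig",
    "simulate_proteome",
    "simulate_sorf_predictions",
    "simulate_spectra",
    "simulate_psm_scores",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_NON_BASIC = "".join(a for a in _ALPHABET if a not in "KR")


@dataclass(frozen=True)
class SpectraConfig:
    n_peptides: int = 50
    noise_peaks_per_spectrum: int = 20
    intensity_model: str = "gamma"  # or "geometric"
    correlation_rho: float = 0.8
    frac_non_tryptic: float = 0.8   # endogenous peptides rarely end on K/R
    len_range: tuple[int, int] = (8, 30)
    rt_span: float = 3600.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation_rho <= 1.0:
            raise ValueError("correlation_rho outside [-1, 1]")
        if self.intensity_model not in ("gamma", "geometric"):
            raise ValueError(f"unknown intensity model {self.intensity_model}")


@dataclass(frozen=True)
class PsmMixtureConfig:
    n_targets: int = 2000
    n_decoys: int = 2000
    pi_correct: float = 0.35
    mu_correct: float = 3.0
    mu_incorrect: float = 0.0
    sigma: float = 1.0
    n_informative_features: int = 3
    feature_effect: float = 1.5
    n_uninformative_features: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_correct < 1.0:
            raise ValueError("pi_correct outside (0, 1)")
        if min(self.n_targets, self.n_decoys) < 0:
            raise ValueError("negative counts")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    venn_cells: tuple[int, ...] = (50, 300, 110, 16, 11, 32, 11)
    seq_len_range: tuple[int, int] = (20, 60)
    n_sorfs: int = 60
    dup_stop_groups: int = 5
    dup_group_size: int = 3
    single_exon_planted: int = 6
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    psm_mixture: PsmMixtureConfig = field(default_factory=PsmMixtureConfig)

    def __post_init__(self) -> None:
        if len(self.venn_cells) != 7 or any(c < 0 for c in self.venn_cells):
            raise ValueError("venn_cells must be 7 non-negative counts")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spectra" in raw:
            raw["spectra"] = SpectraConfig(**{
                k: tuple(v) if k == "len_range" else v
                for k, v in raw["spectra"].items()})
        if "psm_mixture" in raw:
            raw["psm_mixture"] = PsmMixtureConfig(**raw["psm_mixture"])
        for key in ("venn_cells", "seq_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _random_peptide(rng: np.random.Generator, length: int,
                    non_tryptic: bool | None = None) -> str:
    core = "".join(rng.choice(list(_ALPHABET), size=length - 1))
    if non_tryptic is None:
        last = rng.choice(list(_ALPHABET))
    elif non_tryptic:
        last = rng.choice(list(_NON_BASIC))
    else:
        last = rng.choice(["K", "R"])
    return core + last


def _distinct_sequences(rng: np.random.Generator, n: int,
                        len_range: tuple[int, int]) -> list[str]:
    lo, hi = len_range
    if n > 0.01 * 20.0 ** lo:
        raise ValueError(
            f"{n} distinct sequences infeasible for minimum length {lo}")
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = _random_peptide(rng, int(rng.integers(lo, hi + 1)))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


# ---------------------------------------------------------------------------
# Proteome Venn structure
# ---------------------------------------------------------------------------

_CELL_NAMES = ("R_only", "O_only", "S_only", "RO", "RS", "OS", "ROS")
_CELL_MEMBERSHIP = {
    "R_only": ("R",), "O_only": ("O",), "S_only": ("S",),
    "RO": ("R", "O"), "RS": ("R", "S"), "OS": ("O", "S"),
    "ROS": ("R", "O", "S"),
}


def simulate_proteome(config: SimConfig) -> dict:
    """Three sequence sets with exact planted Venn-cell counts.

    Returns reference/openprot/sorfs_org record lists plus the ground-truth
    cell assignment, such that composition accounting must recover the
    planted counts exactly.
    """
    rng = np.random.default_rng(config.seed)
    cells = dict(zip(_CELL_NAMES, config.venn_cells))
    seqs = _distinct_sequences(rng, sum(cells.values()), config.seq_len_range)

    sets: dict[str, list[SeqRecord]] = {"R": [], "O": [], "S": []}
    truth: dict[str, list[str]] = {name: [] for name in _CELL_NAMES}
    source_of = {"R": Source.REFERENCE, "O": Source.OPENPROT,
                 "S": Source.SORFS_ORG}
    prefix_of = {"R": "sp|REF", "O": "IP_", "S": "SORF"}
    i = 0
    for name in _CELL_NAMES:
        for _ in range(cells[name]):
            seq = seqs[i]
            truth[name].append(seq)
            for part in _CELL_MEMBERSHIP[name]:
                rec_id = f"{prefix_of[part]}{i:06d}"
                if part == "R":
                    rec_id += "|GEN"
                sets[part].append(SeqRecord(
                    id=rec_id, description=rec_id, sequence=seq,
                    source=source_of[part]))
            i += 1
    return {
        "reference": sets["R"],
        "openprot": sets["O"],
        "sorfs_org": sets["S"],
        "truth_cells": {k: len(v) for k, v in truth.items()},
        "truth_assignment": truth,
        "seed": config.seed,
    }


# ---------------------------------------------------------------------------
# sORF predictions with planted filtering structure
# ---------------------------------------------------------------------------

def simulate_sorf_predictions(config: SimConfig) -> dict:
    """sORF records with loci, coding exons, and the expected survivors.

    Plants ``dup_stop_groups`` stop-sharing groups (known longest member)
    and ``single_exon_planted`` single-block predictions overlapping coding
    exons; everything else is multi-block with a unique stop and must
    survive both filters.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_group_members = config.dup_stop_groups * config.dup_group_size
    n_background = config.n_sorfs - n_group_members - config.single_exon_planted
    if n_background < 0:
        raise ValueError("planted structures exceed n_sorfs")

    records: list[SeqRecord] = []
    exons: list[ExonInterval] = []
    expected_survivors: list[str] = []
    pos = 1000

    def _seq(length: int) -> str:
        return _random_peptide(rng, length)

    # background: two-block loci, unique stops -> always retained
    for i in range(n_background):
        length = int(rng.integers(20, 60))
        # split the 3*length+3 nt ORF over two blocks (always spliced)
        blocks = ((pos, pos + 30), (pos + 200, pos + 200 + 3 * length + 3 - 30))
        rec = SeqRecord(
            id=f"SORF_BG{i:04d}", description=f"SORF_BG{i:04d}",
            sequence=_seq(length), source=Source.SORFS_ORG,
            locus=Locus(chrom="chr1", strand="+", blocks=blocks))
        records.append(rec)
        expected_survivors.append(rec.id)
        pos += 1000

    # stop-sharing groups: distinct lengths, shared 3'-most coordinate
    for g in range(config.dup_stop_groups):
        stop_end = pos + 600
        lengths = sorted(
            rng.choice(np.arange(20, 60), size=config.dup_group_size,
                       replace=False))
        for m, length in enumerate(lengths):
            blocks = ((stop_end - 3 * length - 3, stop_end),)
            # single-block is fine here: placed away from any coding exon
            rec = SeqRecord(
                id=f"SORF_G{g:02d}M{m}", description=f"group {g}",
                sequence=_seq(int(length)), source=Source.SORFS_ORG,
                locus=Locus(chrom="chr2", strand="+", blocks=blocks))
            records.append(rec)
        expected_survivors.append(f"SORF_G{g:02d}M{config.dup_group_size - 1}")
        pos += 1000

    # planted single-exon predictions inside coding exons -> removed
    for i in range(config.single_exon_planted):
        start = pos
        end = start + 150
        exons.append(ExonInterval(chrom="chr3", start=start - 50,
                                  end=end + 50, strand="+",
                                  name=f"coding_exon_{i}"))
        rec = SeqRecord(
            id=f"SORF_SE{i:03d}", description="single-exon overlap",
            sequence=_seq(int(rng.integers(20, 49))), source=Source.SORFS_ORG,
            locus=Locus(chrom="chr3", strand="+", blocks=((start, end),)))
        records.append(rec)
        pos += 1000

    # decoy exons far from everything
    for i in range(5):
        exons.append(ExonInterval(chrom="chr9", start=i * 10_000,
                                  end=i * 10_000 + 500, strand="-",
                                  name=f"decoy_exon_{i}"))

    return {
        "records": records,
        "coding_exons": exons,
        "expected_survivors": sorted(expected_survivors),
        "seed": config.seed,
    }


# ---------------------------------------------------------------------------
# Spectra with tunable predicted-observed correlation
# ---------------------------------------------------------------------------

def _draw_intensities(rng: np.random.Generator, n: int, model: str) -> np.ndarray:
    if model == "gamma":
        return rng.gamma(shape=2.0, scale=1.0, size=n)
    # geometric-style: dyadic intensity ladder, mimics few dominant ions
    return 2.0 ** -rng.integers(0, 8, size=n).astype(float)


def simulate_spectra(
    config: SimConfig, peptidoforms: list[Peptidoform] | None = None
) -> dict:
    """Spectra whose observed intensities correlate ~rho with predictions.

    The observed vector is a convex mixture of the predicted vector and
    independent noise, constructed in transformed-intensity space so the
    expected post-transform Pearson correlation is ``correlation_rho``.
    Random noise peaks are added away from any theoretical fragment m/z.
    """
    sc = config.spectra
    rng = np.random.default_rng(config.seed + 2)
    if peptidoforms is None:
        peptidoforms = []
        for _ in range(sc.n_peptides):
            length = int(rng.integers(sc.len_range[0], sc.len_range[1] + 1))
            non_tryptic = bool(rng.random() < sc.frac_non_tryptic)
            peptidoforms.append(
                Peptidoform(_random_peptide(rng, length, non_tryptic)))

    spectra: list[Spectrum] = []
    predicted: dict[str, np.ndarray] = {}
    rho = sc.correlation_rho
    for k, p in enumerate(peptidoforms):
        frags = fragment_mz(p, max_frag_charge=1)
        theo = frags.vector_mz(charges=(1,))
        pred = _draw_intensities(rng, len(theo), sc.intensity_model)

        if rho >= 1.0:
            obs = pred.copy()
        else:
            t_pred = transform_intensities(pred)
            noise = _draw_intensities(rng, len(theo), sc.intensity_model)
            t_noise = transform_intensities(noise)
            mu, sd = t_pred.mean(), t_pred.std()
            z_p = (t_pred - mu) / sd if sd > 0 else np.zeros_like(t_pred)
            nsd = t_noise.std()
            z_n = ((t_noise - t_noise.mean()) / nsd
                   if nsd > 0 else rng.standard_normal(len(theo)))
            z_o = rho * z_p + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z_n
            t_obs = np.clip(mu + sd * z_o, 0.0, None)
            obs = (2.0 ** t_obs - 1.0) / 1.0e4

        charge = int(rng.integers(1, 7))
        mz = list(theo)
        inten = list(obs)
        for _ in range(sc.noise_peaks_per_spectrum):
            while True:
                cand = float(rng.uniform(100.0, 1500.0))
                if np.all(np.abs(theo - cand) > 0.05):
                    break
            mz.append(cand)
            inten.append(float(_draw_intensities(rng, 1, sc.intensity_model)[0]
                               * 0.2))
        sid = f"scan={k:05d}"
        spectra.append(Spectrum(
            spectrum_id=sid,
            precursor_mz=(monoisotopic_mass(p) + charge * PROTON_MASS) / charge,
            precursor_charge=charge,
            peaks_mz=np.array(mz),
            peaks_intensity=np.array(inten),
            rt=float(rng.uniform(0.0, sc.rt_span)),
        ))
        predicted[sid] = pred
    return {
        "spectra": spectra,
        "predicted": predicted,
        "peptidoforms": peptidoforms,
        "seed": config.seed,
    }


def write_predicted_intensities(predicted: dict[str, np.ndarray], path: str) -> None:
    """Write the predicted-intensity TSV (columns i0.. padded with NaN)."""
    width = max(len(v) for v in predicted.values())
    rows = []
    for sid, vec in predicted.items():
        row: dict = {"spectrum_id": sid}
        for j in range(width):
            row[f"i{j}"] = vec[j] if j < len(vec) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSM score mixtures for FDR calibration
# ---------------------------------------------------------------------------

def simulate_psm_scores(config: SimConfig) -> pd.DataFrame:
    """Two-Gaussian target/decoy score mixture with correctness labels.

    Correct targets draw base scores from N(mu_correct, sigma); incorrect
    targets and all decoys from N(mu_incorrect, sigma). Informative features
    are shifted by ``feature_effect`` for correct PSMs only; uninformative
    features are standard normal for everyone. The returned frame follows
    the PSM TSV dialect plus an ``is_correct`` ground-truth column.
    """
    pc = config.psm_mixture
    rng = np.random.default_rng(config.seed + 3)
    n = pc.n_targets + pc.n_decoys
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[pc.n_targets:] = True
    is_correct = np.zeros(n, dtype=bool)
    is_correct[:pc.n_targets] = rng.random(pc.n_targets) < pc.pi_correct

    base = rng.normal(pc.mu_incorrect, pc.sigma, size=n)
    base[is_correct] = rng.normal(pc.mu_correct, pc.sigma,
                                  size=int(is_correct.sum()))

    data: dict = {
        "psm_id": [f"psm_{i:06d}" for i in range(n)],
        "spectrum_id": [f"scan={i:06d}" for i in range(n)],
        "sample_id": ["sim_brain"] * n,
        "replicate_id": ["rep1"] * n,
        "sequence": [_random_peptide(rng, int(rng.integers(8, 31)))
                     for _ in range(n)],
        "mods": [""] * n,
        "charge": rng.integers(1, 7, size=n),
        "is_decoy": is_decoy,
        "protein_ids": np.where(is_decoy, "DECOY_PROT", "PROT"),
        "base_score": base,
        "observed_rt": rng.uniform(0, 3600, size=n),
    }
    data["predicted_rt"] = data["observed_rt"] + rng.normal(0, 60, size=n)
    for j in range(pc.n_informative_features):
        feat = rng.standard_normal(n)
        feat[is_correct] += pc.feature_effect
        data[f"feat_inf{j}"] = feat
    for j in range(pc.n_uninformative_features):
        data[f"feat_rand{j}"] = rng.standard_normal(n)
    df = pd.DataFrame(data)
    df["is_correct"] = is_correct
    return df


def write_truth(payload: dict, path: str) -> None:
    """Dump generator ground truth (including the seed) as JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
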
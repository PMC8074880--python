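"""Seeded generators emulating the statistical structure of the three data
streams: fossil occurrences with dental morphotypes, jaw-length records, and
group-structured 33-landmark jaw shapes.

The generators reproduce the qualitative patterns the real data show —

* a homogeneous-to-heterogeneous shift in dental morphotype composition
  across the 14 stage bins (early assemblages dominated by simple conical
  teeth, later ones spread across all eight categories);
* a mid-sequence appearance of large marine taxa in the size series
  (emulating the Cenomanian mosasauroid expansion);
* epoch-structured jaw shapes built from a template mandible plus smooth
  deformation modes with controllable between-group offsets, within-group
  spread and landmark noise, hidden behind random rigid motions and
  scalings so superimposition has real work to do.

Every generator is deterministic given (config, seed) and returns its ground
truth alongside the data, so recovery tests can check the injected signal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .morphometry import LandmarkSet, N_LANDMARKS
from .stratigraphy import StageTable, default_stage_table

__all__ = [
    "SyntheticConfig",
    "load_template_jaw",
    "deformation_modes",
    "gen_occurrences",
    "gen_sizes",
    "gen_shapes",
    "write_occurrence_files",
    "write_size_file",
    "write_shape_files",
]

MORPHOTYPES = (
    "conical", "compressed-pointed-recurved", "hooked-slender", "bicuspid",
    "tricuspid", "polycuspid-leaf-shaped", "crushing", "other-specialised",
)


@dataclass
class SyntheticConfig:
    """Generating conditions for the three synthetic data streams.

    Defaults mirror the study conditions: 220 genera with dental
    assignments over 14 stages, 116 jaw-length records, and epoch shape
    samples of 5 / 13 / 74 (Late Jurassic / Early Cretaceous / Late
    Cretaceous). The composition regime switches at the Cenomanian from a
    conical-dominated early vector to a heterogeneous late vector; marine
    large-bodied taxa enter the size series at the same stage.
    """

    seed: int = 0

    # occurrences + dental morphotypes
    n_genera: int = 220
    heterodonty_prob: float = 0.15
    regime_onset_stage: str = "Cenomanian"
    early_composition: tuple = (0.75, 0.15, 0.10, 0.0, 0.0, 0.0, 0.0, 0.0)
    late_composition: tuple = (0.30, 0.20, 0.10, 0.08, 0.08, 0.08, 0.08, 0.08)
    marine_fraction: float = 0.20      # fraction of post-onset genera that are marine
    mean_duration_stages: float = 1.5  # mean range length (geometric)

    # jaw sizes
    n_sizes: int = 116
    terrestrial_log10_mean: float = 1.5   # ~32 mm
    terrestrial_log10_sd: float = 0.35
    marine_log10_mean: float = 2.4        # ~250 mm (mosasauroid-grade)
    marine_log10_sd: float = 0.45
    marine_onset_stage: str = "Cenomanian"
    marine_size_fraction: float = 0.35    # fraction of post-onset size records marine

    # jaw shapes
    shape_group_sizes: dict = field(default_factory=lambda: {
        "Late Jurassic": 5, "Early Cretaceous": 13, "Late Cretaceous": 74})
    group_offsets: dict = field(default_factory=lambda: {
        "Late Jurassic": (0.0, 0.0, 0.0),
        "Early Cretaceous": (0.03, 0.0, 0.0),
        "Late Cretaceous": (0.02, 0.02, 0.0)})
    group_spreads: dict = field(default_factory=lambda: {
        "Late Jurassic": (0.02, 0.02, 0.01),
        "Early Cretaceous": (0.03, 0.02, 0.01),
        "Late Cretaceous": (0.06, 0.05, 0.03)})
    shape_noise_sd: float = 0.004
    n_snakes: int = 6          # Late Cretaceous taxa labelled as snakes
    snake_offset: tuple = (0.12, -0.02, 0.0)   # snakes sit at a morphospace extreme
    scale_range: tuple = (0.2, 5.0)
    translation_range: float = 10.0

    def validate(self) -> None:
        for vec in (self.early_composition, self.late_composition):
            if len(vec) != len(MORPHOTYPES):
                raise ValueError("composition vectors must have 8 entries")
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError("composition vectors must be probability vectors")
        if not self.shape_noise_sd >= 0:
            raise ValueError("shape_noise_sd must be >= 0")
        if not 0 <= self.heterodonty_prob <= 1:
            raise ValueError("heterodonty_prob must be in [0, 1]")


def load_template_jaw() -> np.ndarray:
    """The packaged 33-point template mandible (unit jaw length)."""
    text = resources.files("squamorph.data").joinpath("template_jaw.csv").read_text()
    rows = [r for r in csv.reader(text.splitlines()) if r and not r[0].startswith("#")]
    pts = np.array([[float(x), float(y)] for x, y in rows[1:]])
    assert pts.shape == (N_LANDMARKS, 2)
    return pts


def deformation_modes(template: Optional[np.ndarray] = None) -> np.ndarray:
    """Three smooth, unit-norm deformation modes of the template jaw.

    Mode 0 stretches the anterior biting region (elongation), mode 1 raises
    the coronoid region, mode 2 thickens the ramus dorsoventrally
    (robusticity). Each is normalised to unit Frobenius norm so mode
    coefficients are directly comparable.
    """
    t = load_template_jaw() if template is None else template
    x, y = t[:, 0], t[:, 1]
    modes = np.zeros((3, N_LANDMARKS, 2))
    modes[0, :, 0] = x - x.mean()                       # elongation
    modes[1, :, 1] = np.exp(-((x - 0.22) ** 2) / (2 * 0.08 ** 2)) * (y > 0.05)
    modes[2, :, 1] = np.sign(y - y.mean()) * np.abs(y - y.mean())
    for i in range(3):
        modes[i] /= np.linalg.norm(modes[i])
    return modes


# ---------------------------------------------------------------------------
# occurrences + dental morphotypes

def _sample_range(rng: np.random.Generator, n_stages: int,
                  mean_duration: float) -> tuple[int, int]:
    # FAD weighted towards younger stages (the empirical sampling ramp)
    weights = np.linspace(1.0, 3.0, n_stages)
    weights /= weights.sum()
    fad = int(rng.choice(n_stages, p=weights))
    dur = int(rng.geometric(1.0 / mean_duration)) - 1
    lad = min(fad + dur, n_stages - 1)
    return fad, lad


def gen_occurrences(cfg: SyntheticConfig,
                    table: Optional[StageTable] = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate occurrence records and dental morphotype assignments.

    Each genus gets a stage range; its morphotype draw comes from the
    composition regime active at its first-appearance stage (early vector
    before the onset stage, late vector from it onward). Heterodont taxa
    receive a second distinct code with probability ``heterodonty_prob``.

    Returns (occurrences, assignments, ground_truth).
    """
    cfg.validate()
    table = table or default_stage_table()
    rng = np.random.default_rng(cfg.seed)
    onset = table.index(cfg.regime_onset_stage)
    early = np.asarray(cfg.early_composition)
    late = np.asarray(cfg.late_composition)
    occ_rows, morph_rows = [], []
    for i in range(cfg.n_genera):
        genus = f"Synthgenus_{i:04d}"
        fad, lad = _sample_range(rng, len(table), cfg.mean_duration_stages)
        post_onset = fad >= onset
        marine = post_onset and rng.random() < cfg.marine_fraction
        regime = late if post_onset else early
        codes = {MORPHOTYPES[rng.choice(len(MORPHOTYPES), p=regime)]}
        if rng.random() < cfg.heterodonty_prob:
            codes.add(MORPHOTYPES[rng.choice(len(MORPHOTYPES), p=regime)])
        occ_rows.append({
            "genus": genus,
            "fad_stage": table.names[fad],
            "lad_stage": table.names[lad],
            "habitat": "marine" if marine else "terrestrial",
            "clade": "mosasauroid" if marine else "lizard",
            "diet": "",
        })
        morph_rows.append({"genus": genus,
                           "morphotypes": ";".join(sorted(codes))})
    truth = {
        "regime_onset_stage": cfg.regime_onset_stage,
        "early_composition": list(early),
        "late_composition": list(late),
        "heterodonty_prob": cfg.heterodonty_prob,
        "seed": cfg.seed,
    }
    return pd.DataFrame(occ_rows), pd.DataFrame(morph_rows), truth


# ---------------------------------------------------------------------------
# jaw sizes

def gen_sizes(cfg: SyntheticConfig,
              table: Optional[StageTable] = None) -> tuple[pd.DataFrame, dict]:
    """Generate jaw-length records (mm).

    Lengths are lognormal per habitat (parameters on the log10 scale);
    marine, large-bodied taxa are present only from the configured onset
    stage, with a larger location parameter, emulating the mid-Cretaceous
    marine expansion. Ground truth records the injected location/scale shift.
    """
    cfg.validate()
    table = table or default_stage_table()
    rng = np.random.default_rng(cfg.seed + 1)
    onset = table.index(cfg.marine_onset_stage)
    rows = []
    for i in range(cfg.n_sizes):
        genus = f"Synthsize_{i:04d}"
        fad, lad = _sample_range(rng, len(table), cfg.mean_duration_stages)
        marine = fad >= onset and rng.random() < cfg.marine_size_fraction
        if marine:
            log10_len = rng.normal(cfg.marine_log10_mean, cfg.marine_log10_sd)
            clade = "mosasauroid"
        else:
            log10_len = rng.normal(cfg.terrestrial_log10_mean, cfg.terrestrial_log10_sd)
            clade = "lizard"
        rows.append({
            "genus": genus,
            "jaw_length_mm": round(10.0 ** log10_len, 3),
            "habitat": "marine" if marine else "terrestrial",
            "clade": clade,
            "fad_stage": table.names[fad],
            "lad_stage": table.names[lad],
        })
    truth = {
        "marine_onset_stage": cfg.marine_onset_stage,
        "terrestrial_log10_mean": cfg.terrestrial_log10_mean,
        "terrestrial_log10_sd": cfg.terrestrial_log10_sd,
        "marine_log10_mean": cfg.marine_log10_mean,
        "marine_log10_sd": cfg.marine_log10_sd,
        "seed": cfg.seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# jaw shapes

def gen_shapes(cfg: SyntheticConfig
               ) -> tuple[list[LandmarkSet], pd.DataFrame, dict]:
    """Generate group-structured 33-landmark jaw shapes.

    shape = template + Σ_k (group_offset_k + N(0, group_spread_k)) · mode_k
            + isotropic landmark noise,
    then a random rigid motion and scaling are applied and a side (left or
    right) assigned at random — so mirroring and superimposition are
    exercised, not bypassed. Some Late Cretaceous taxa are labelled snakes
    and displaced towards a morphospace extreme.

    Returns (shapes, metadata, ground_truth); metadata carries taxon, epoch,
    clade and diet columns, and ground truth the per-taxon mode coefficients.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    template = load_template_jaw()
    modes = deformation_modes(template)
    shapes: list[LandmarkSet] = []
    meta_rows = []
    coeff_truth = {}
    idx = 0
    for epoch, n in cfg.shape_group_sizes.items():
        offs = np.asarray(cfg.group_offsets[epoch], dtype=float)
        sprd = np.asarray(cfg.group_spreads[epoch], dtype=float)
        snake_slots = set()
        if epoch == "Late Cretaceous" and cfg.n_snakes > 0:
            snake_slots = set(range(max(0, n - cfg.n_snakes), n))
        for j in range(n):
            taxon = f"Synthshape_{idx:04d}"
            coeffs = offs + rng.normal(0.0, 1.0, size=3) * sprd
            clade, diet = "lizard", "carnivore"
            if j in snake_slots:
                coeffs = coeffs + np.asarray(cfg.snake_offset)
                clade, diet = "snake", "carnivore"
            pts = template + np.tensordot(coeffs, modes, axes=1)
            if cfg.shape_noise_sd > 0:
                pts = pts + rng.normal(0.0, cfg.shape_noise_sd, size=pts.shape)
            # random similarity transform + side flip to exercise GPA
            theta = rng.uniform(-np.pi, np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            scale = rng.uniform(*cfg.scale_range)
            shift = rng.uniform(-cfg.translation_range, cfg.translation_range, size=2)
            obs = pts @ rot.T * scale + shift
            side = "right" if rng.random() < 0.5 else "left"
            if side == "left":
                obs = obs.copy()
                obs[:, 0] = -obs[:, 0]
            shapes.append(LandmarkSet(taxon=taxon, points=obs, side=side,
                                      metadata={"epoch": epoch, "clade": clade,
                                                "diet": diet}))
            meta_rows.append({"taxon": taxon, "epoch": epoch, "clade": clade,
                              "diet": diet, "side": side})
            coeff_truth[taxon] = coeffs.tolist()
            idx += 1
    truth = {
        "group_offsets": {k: list(v) for k, v in cfg.group_offsets.items()},
        "group_spreads": {k: list(v) for k, v in cfg.group_spreads.items()},
        "snake_offset": list(cfg.snake_offset),
        "shape_noise_sd": cfg.shape_noise_sd,
        "mode_coefficients": coeff_truth,
        "seed": cfg.seed,
    }
    return shapes, pd.DataFrame(meta_rows), truth


# ---------------------------------------------------------------------------
# file emission (the exact CSV/TPS dialects the analysis modules consume)

def write_occurrence_files(cfg: SyntheticConfig, outdir: str | Path,
                           table: Optional[StageTable] = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    occ, morph, truth = gen_occurrences(cfg, table)
    occ_path = outdir / "occurrences.csv"
    morph_path = outdir / "morphotypes.csv"
    occ.to_csv(occ_path, index=False)
    morph.to_csv(morph_path, index=False)
    truth_path = outdir / "occurrences_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"occurrences": occ_path, "morphotypes": morph_path, "truth": truth_path}


def write_size_file(cfg: SyntheticConfig, outdir: str | Path,
                    table: Optional[StageTable] = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes, truth = gen_sizes(cfg, table)
    path = outdir / "jaw_lengths.csv"
    sizes.to_csv(path, index=False)
    truth_path = outdir / "jaw_lengths_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"jaw_lengths": path, "truth": truth_path}


def write_shape_files(cfg: SyntheticConfig, outdir: str | Path) -> dict:
    from .morphometry import write_tps
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shapes, meta, truth = gen_shapes(cfg)
    tps_path = outdir / "jaw_shapes.tps"
    write_tps(tps_path, shapes)
    meta_path = outdir / "jaw_shapes_meta.csv"
    meta.to_csv(meta_path, index=False)
    truth_path = outdir / "jaw_shapes_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"tps": tps_path, "metadata": meta_path, "truth": truth_path}


def _config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
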
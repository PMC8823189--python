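"""Seeded generator of a complete synthetic paired bed-rest study.

The generator emulates the structure of a two-arm, five-week bed-rest
muscle RNA-seq study: five male subject pairs (one control, one exercise
subject each) plus one female trio, two biopsies per subject (baseline and
post-intervention), strongly correlated baselines across subjects, a large
control-specific set of planted differentially expressed genes and a much
smaller exercise-specific set with a shared same-direction / opposing
overlap structure, marker genes with a configured direction in the control
arm, library sizes on the scale of real deep bulk libraries, a
ligand-receptor pair table against a target-tissue (DRG) receptor profile,
and junction bridge-read counts for a targeted exon inclusion/skipping
event.  Every planted quantity is exported as :class:`GroundTruth` so that
downstream stages can be scored exactly.

Generative model
----------------
A shared gene profile ``x_g`` is drawn log-normally (``ln x_g ~
N(baseline_log_mean, baseline_log_sd^2)``).  Subject baselines multiply the
profile by per-(gene, subject) biological noise ``2^a``, ``a ~ N(0,
baseline_subject_sd^2)``; post-intervention samples multiply the baseline
by ``2^(beta_g + b)`` where ``beta_g`` is the planted signed effect of the
subject's intervention group (zero off the group's DEG set) and ``b ~ N(0,
noise_sd^2)``.  Junction counts are Poisson with expectation
``planted_rpm * library_size / 1e6``, so the planted level is the true RPM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_pairs: int = 5
    include_female_trio: bool = True
    n_genes: int = 12_000
    coding_fraction: float = 0.9
    baseline_log_mean: float = 1.0   # natural-log mean of the shared TPM profile
    baseline_log_sd: float = 1.5     # natural-log sd of the shared TPM profile
    baseline_subject_sd: float = 0.2  # per-subject biological noise, log2 scale
    noise_sd: float = 0.3            # within-subject post-vs-baseline noise, log2
    n_deg_control: int = 300
    n_deg_exercise: int = 30
    n_shared_same_direction: int = 8
    n_shared_opposing: int = 4
    effect_mean: float = 1.2         # mean of |log2FC| of planted effects
    effect_sd: float = 0.3           # sd of |log2FC| of planted effects
    marker_genes: tuple[str, ...] = ("XIRP1", "TNFRSF12A", "HSPB1")
    marker_direction_in_control: int = 1   # +1: up in control, -1: down
    library_size_range: tuple[int, int] = (15_000_000, 35_000_000)
    trio_library_size_range: tuple[int, int] = (75_000_000, 92_000_000)
    # ligand-receptor assets
    n_interactome_ligands: int = 5   # planted up-control DEG ligands with an expressed receptor
    n_decoy_ligands: int = 3         # up-control DEG ligands whose receptors are all unexpressed
    receptor_tau: float = 1.0        # TPM threshold for "expressed in DRG"
    # junction assets (targeted exon inclusion/skipping event)
    junction_exon_length_bp: int = 126
    inclusion_rpm: dict = field(
        default_factory=lambda: {"control": 1.2, "exercise": 0.55}
    )
    skipping_rpm: dict = field(
        default_factory=lambda: {"control": 0.4, "exercise": 0.9}
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pairs, self.n_genes) < 1:
            raise ValueError("n_pairs and n_genes must be positive")
        if not 0.0 <= self.coding_fraction <= 1.0:
            raise ValueError("coding_fraction must be in [0, 1]")
        for name in ("n_deg_control", "n_deg_exercise", "n_shared_same_direction",
                     "n_shared_opposing", "n_interactome_ligands", "n_decoy_ligands"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_shared = self.n_shared_same_direction + self.n_shared_opposing
        if n_shared > min(self.n_deg_control, self.n_deg_exercise):
            raise ValueError(
                "infeasible overlap: shared DEGs exceed the smaller group DEG set"
            )
        n_coding = int(round(self.n_genes * self.coding_fraction))
        if self.n_deg_control + self.n_deg_exercise - n_shared > n_coding:
            raise ValueError("infeasible DEG counts: more DEGs than coding genes")


@dataclass
class GroundTruth:
    """Planted quantities of one simulated study (all seeds recorded)."""

    intervention: dict[str, str]                 # subject_id -> control/exercise
    deg_effects: dict[str, dict[str, float]]     # group -> {gene_id: signed log2FC}
    marker_gene_ids: dict[str, str]              # symbol -> gene_id
    marker_direction_in_control: int
    shared_same_direction: list[str]
    shared_opposing: list[str]
    interactome: dict[str, list[str]] = field(default_factory=dict)
    decoy_ligands: list[str] = field(default_factory=list)
    junction_rpm: dict[str, dict[str, float]] = field(default_factory=dict)

    def deg_set(self, group: str) -> set[str]:
        return set(self.deg_effects[group])

    def upregulated(self, group: str) -> set[str]:
        return {g for g, e in self.deg_effects[group].items() if e > 0}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _subject_layout(config: SimulationConfig, rng: np.random.Generator):
    """Subjects, pairs and randomized within-pair intervention assignment."""
    rows = []
    intervention: dict[str, str] = {}
    for i in range(1, config.n_pairs + 1):
        a, b = f"{i}A", f"{i}B"
        flip = bool(rng.integers(0, 2))
        intervention[a] = "exercise" if flip else "control"
        intervention[b] = "control" if flip else "exercise"
        age = int(rng.integers(19, 50))
        for s in (a, b):
            rows.append((s, f"Pair {i}", "M", age))
    if config.include_female_trio:
        i = config.n_pairs + 1
        trio = [f"{i}A", f"{i}B1", f"{i}B2"]
        intervention[trio[0]] = "control"
        intervention[trio[1]] = intervention[trio[2]] = "exercise"
        age = int(rng.integers(19, 50))
        for s in trio:
            rows.append((s, "Trio female", "F", age))
    return rows, intervention


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression, sample sheet, gene catalog, ground truth).

    Deterministic given ``config.seed``.  The expression matrix is in raw
    (not yet coding-renormalized) TPM units.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    n_coding = int(round(config.n_genes * config.coding_fraction))
    gene_ids = [f"G{i:06d}" for i in range(1, config.n_genes + 1)]
    symbols = [f"SYM{i:06d}" for i in range(1, config.n_genes + 1)]
    is_coding = np.zeros(config.n_genes, dtype=bool)
    is_coding[:n_coding] = True

    # --- planted DEG sets with overlap structure (coding genes only)
    n_shared = config.n_shared_same_direction + config.n_shared_opposing
    n_pick = config.n_deg_control + config.n_deg_exercise - n_shared
    picked = rng.choice(n_coding, size=n_pick, replace=False)
    shared = picked[:n_shared]
    shared_same = shared[: config.n_shared_same_direction]
    shared_opp = shared[config.n_shared_same_direction:]
    control_only = picked[n_shared: n_shared + (config.n_deg_control - n_shared)]
    exercise_only = picked[n_shared + (config.n_deg_control - n_shared):]

    def draw_effects(idx: np.ndarray, signs: np.ndarray) -> dict[str, float]:
        mags = np.abs(rng.normal(config.effect_mean, config.effect_sd, size=len(idx)))
        return {gene_ids[i]: float(s * m) for i, s, m in zip(idx, signs, mags)}

    sign_shared_same = rng.choice([-1.0, 1.0], size=len(shared_same))
    sign_shared_opp = rng.choice([-1.0, 1.0], size=len(shared_opp))
    sign_control_only = rng.choice([-1.0, 1.0], size=len(control_only))
    sign_exercise_only = rng.choice([-1.0, 1.0], size=len(exercise_only))

    deg_control = {}
    deg_control.update(draw_effects(shared_same, sign_shared_same))
    deg_control.update(draw_effects(shared_opp, sign_shared_opp))
    deg_control.update(draw_effects(control_only, sign_control_only))
    deg_exercise = {}
    deg_exercise.update(draw_effects(shared_same, sign_shared_same))
    deg_exercise.update(draw_effects(shared_opp, -sign_shared_opp))
    deg_exercise.update(draw_effects(exercise_only, sign_exercise_only))

    # --- marker genes: control-only DEGs forced to the configured direction
    marker_gene_ids: dict[str, str] = {}
    n_markers = len(config.marker_genes)
    if n_markers > len(control_only):
        raise ValueError("not enough control-only DEGs to host the marker genes")
    for sym, idx in zip(config.marker_genes, control_only[:n_markers]):
        gid = gene_ids[idx]
        marker_gene_ids[sym] = gid
        symbols[idx] = sym
        deg_control[gid] = float(
            config.marker_direction_in_control * abs(deg_control[gid])
        )

    catalog = pd.DataFrame({"gene_id": gene_ids, "symbol": symbols, "is_coding": is_coding})

    # --- subject layout and sample sheet
    rows, intervention = _subject_layout(config, rng)
    sheet_rows = []
    for subject, pair, sex, age in rows:
        lo, hi = (
            config.trio_library_size_range if sex == "F" else config.library_size_range
        )
        for tp, suffix in (("baseline", "Pre"), ("post", "Post")):
            sheet_rows.append(
                {
                    "sample_id": f"{subject}-{suffix}",
                    "subject_id": subject,
                    "pair_id": pair,
                    "sex": sex,
                    "intervention": intervention[subject],
                    "timepoint": tp,
                    "age": age,
                    "mapped_genic_reads": int(rng.integers(lo, hi + 1)),
                }
            )
    sheet = pd.DataFrame(sheet_rows)

    # --- expression: shared profile, subject baselines, planted post effects
    profile = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes))
    effect_vec = {
        grp: np.zeros(config.n_genes)
        for grp in ("control", "exercise")
    }
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for grp, effects in (("control", deg_control), ("exercise", deg_exercise)):
        for gid, e in effects.items():
            effect_vec[grp][gene_pos[gid]] = e

    cols: dict[str, np.ndarray] = {}
    for subject, _pair, _sex, _age in rows:
        a = rng.normal(0.0, config.baseline_subject_sd, config.n_genes)
        baseline = profile * np.exp2(a)
        b = rng.normal(0.0, config.noise_sd, config.n_genes)
        post = baseline * np.exp2(effect_vec[intervention[subject]] + b)
        cols[f"{subject}-Pre"] = baseline
        cols[f"{subject}-Post"] = post
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    values = values[[r["sample_id"] for r in sheet_rows]]

    truth = GroundTruth(
        intervention=intervention,
        deg_effects={"control": deg_control, "exercise": deg_exercise},
        marker_gene_ids=marker_gene_ids,
        marker_direction_in_control=config.marker_direction_in_control,
        shared_same_direction=sorted(gene_ids[i] for i in shared_same),
        shared_opposing=sorted(gene_ids[i] for i in shared_opp),
        junction_rpm={
            "inclusion": dict(config.inclusion_rpm),
            "skipping": dict(config.skipping_rpm),
        },
    )
    return ExpressionMatrix(values=values), sheet, catalog, truth


def simulate_lr_assets(
    config: SimulationConfig,
    truth: GroundTruth,
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build a ligand-receptor pair table and a DRG receptor profile.

    A configured number of planted *upregulated control* DEGs become
    ligands with at least one receptor whose DRG abundance is at or above
    ``receptor_tau``; a further set of decoy ligands map only to receptors
    strictly below the threshold.  The implied true interactome rows
    (receptors in descending abundance) are written into ``truth``.
    """
    rng = np.random.default_rng([config.seed, 1])
    sym = catalog.set_index("gene_id")["symbol"]
    up = sorted(truth.upregulated("control") - set(truth.marker_gene_ids.values()))
    n_need = config.n_interactome_ligands + config.n_decoy_ligands
    if n_need > len(up):
        raise ValueError("not enough upregulated control DEGs for the requested ligands")
    chosen = [up[i] for i in rng.choice(len(up), size=n_need, replace=False)] if n_need else []
    real = chosen[: config.n_interactome_ligands]
    decoys = chosen[config.n_interactome_ligands:]

    pair_rows = []
    receptor_tpm: dict[str, float] = {}
    tau = config.receptor_tau
    truth.interactome = {}
    truth.decoy_ligands = sorted(sym[g] for g in decoys)
    r = 0
    for gid in real:
        lig = sym[gid]
        n_rec = int(rng.integers(1, 4))
        recs = []
        for _ in range(n_rec):
            r += 1
            rec = f"RCPT{r:03d}"
            # first receptor guaranteed expressed; the rest mixed
            expressed = len(recs) == 0 or bool(rng.integers(0, 2))
            tpm = float(rng.uniform(tau + 0.5, tau + 50)) if expressed else float(
                rng.uniform(0, max(tau - 1e-9, 0))
            )
            receptor_tpm[rec] = tpm
            recs.append(rec)
            pair_rows.append({"ligand": lig, "receptor": rec})
        expressed_recs = [x for x in recs if receptor_tpm[x] >= tau]
        expressed_recs.sort(key=lambda x: (-receptor_tpm[x], x))
        truth.interactome[lig] = expressed_recs
    for gid in decoys:
        lig = sym[gid]
        r += 1
        rec = f"RCPT{r:03d}"
        receptor_tpm[rec] = float(rng.uniform(0, max(tau - 1e-9, 0)))
        pair_rows.append({"ligand": lig, "receptor": rec})

    pairs = pd.DataFrame(pair_rows, columns=["ligand", "receptor"])
    profile = pd.Series(receptor_tpm, name="tpm", dtype=float)
    profile.index.name = "gene"
    return pairs, profile


def simulate_junction_counts(
    config: SimulationConfig,
    sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson junction bridge-read counts for the targeted splice event.

    Returns (counts, metadata).  Counts have expectation
    ``planted_rpm[group] * mapped_genic_reads / 1e6`` per sample, so the
    planted level is exactly the true RPM.
    """
    rng = np.random.default_rng([config.seed, 2])
    meta = pd.DataFrame(
        [
            {"junction_id": "JX_INCL", "exon_id": "EX_TARGET",
             "exon_length_bp": config.junction_exon_length_bp, "role": "inclusion"},
            {"junction_id": "JX_SKIP", "exon_id": "EX_TARGET",
             "exon_length_bp": config.junction_exon_length_bp, "role": "skipping"},
        ]
    )
    planted = {"JX_INCL": config.inclusion_rpm, "JX_SKIP": config.skipping_rpm}
    rows = []
    for _, s in sheet.iterrows():
        for jx in ("JX_INCL", "JX_SKIP"):
            rpm = planted[jx][s["intervention"]]
            lam = rpm * s["mapped_genic_reads"] / 1e6
            rows.append(
                {
                    "sample_id": s["sample_id"],
                    "junction_id": jx,
                    "count": int(rng.poisson(lam)) if lam > 0 else 0,
                }
            )
    return pd.DataFrame(rows), meta
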
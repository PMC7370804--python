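"""Seeded synthetic microcosm experiments.

Generates self-contained fixture datasets with the statistical structure the
analysis modules assume: a design table of microcosms along a strain-richness
gradient under different grazer regimes, daily community trajectories with
strain-resolved invader biomass (ground truth), multinomially sampled
amplicon reads from the strain composition, microscopy-style census tables
and particulate C/N/P masses.

The community model is a minimal discrete-time simulation — it is NOT an
attempt to fit any real system; it only has to reproduce the qualitative
regimes the analysis must handle:

* logistic growth limited by a shared carrying capacity (resource
  competition between residents and invader strains),
* per-strain growth rates (strain identity effects) and a small seeded
  lognormal jitter of resident rates per microcosm (replicate noise),
* type-dependent grazing mortality: a generalist grazer at high density
  removes the invader faster than it can grow (consumptive resistance,
  invasion fails); at low density the grazer collapses and invasion
  succeeds late; a specialist grazer suppresses residents more than the
  invader, so consumer and invader coexist at a high invader share; no
  grazer lets the invader dominate,
* chemostat-style dilution of all biomass.

Per-day update for biomass ``B`` of species/strain ``i``::

    B_i(t+1) = B_i(t) · exp( r_i · (1 − T(t)/K) − a · G(t) · s_i − δ )

with total biomass T, carrying capacity K, grazer density G(t) following a
regime-specific deterministic trajectory, attack rate a, susceptibility s_i
(scaled by a regime-specific preference for residents vs invader) and
dilution δ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .biovolume import ShapeSpec, cell_volume
from .demux import MarkerDB, reverse_complement
from .stats import MicrocosmDesign

HERBIVORE_REGIMES = ("none", "generalist_high", "generalist_low", "specialist")

#: regime -> (initial grazer density [ml⁻¹], per-day growth rate of the
#: grazer trajectory, susceptibility multiplier for residents, for invader)
_REGIME_PARAMS = {
    "none": (0.0, 0.0, 0.0, 0.0),
    "generalist_high": (1.5, 0.0, 0.05, 1.0),
    "generalist_low": (0.2, -0.25, 0.05, 1.0),
    "specialist": (1.0, 0.0, 0.05, 0.25),
}

#: grazer attack rate, (animals ml⁻¹)⁻¹ day⁻¹
_ATTACK_RATE = 1.6


def per_strain_inoculum(total_invader_inoculum: float, diversity_level: int) -> float:
    """Substitutive design: the total invader inoculum is split equally,
    so each of k strains enters at total/k μg ml⁻¹."""
    if total_invader_inoculum <= 0:
        raise ValueError("total inoculum must be > 0")
    if diversity_level < 1:
        raise ValueError("diversity level must be ≥ 1")
    return total_invader_inoculum / diversity_level


@dataclass(frozen=True)
class StrainTrait:
    """Phenotype of one invader strain."""

    strain_id: str
    growth_rate: float  # day⁻¹
    grazing_susceptibility: float  # dimensionless, 0–1
    marker_copy_bias: float = 1.0  # multiplicative factor in read generation

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be ≥ 0")
        if not 0.0 <= self.grazing_susceptibility <= 1.0:
            raise ValueError("grazing_susceptibility must be in [0, 1]")
        if self.marker_copy_bias <= 0:
            raise ValueError("marker_copy_bias must be > 0")


@dataclass
class SimulationConfig:
    """All tunables of one synthetic experiment."""

    n_resident_species: int = 8
    herbivore_regime: str = "specialist"
    total_invader_inoculum: float = 0.1  # μg ml⁻¹ (5% of resident biomass)
    resident_total_inoculum: float = 2.0  # μg ml⁻¹
    diversity_levels: Sequence[int] = (1, 3, 6, 10)
    replicates_per_level: Sequence[int] = (2, 5, 5, 3)
    duration_days: int = 38
    seed: int = 0
    # generator knobs beyond the experimental design
    n_strains: int = 10
    invasion_day: int = 6
    sampling_offsets: Sequence[int] = (0, 8, 32)  # days after invasion
    carrying_capacity: float = 12.0  # μg ml⁻¹
    resident_growth_rate: float = 0.35  # day⁻¹
    resident_rate_cv: float = 0.08  # lognormal replicate jitter
    dilution: float = 0.1  # day⁻¹ (20% medium exchange every second day)
    read_depth: int = 10_000
    read_error_rate: float = 0.0
    rc_probability: float = 0.5
    marker_length: int = 120

    def __post_init__(self) -> None:
        if self.herbivore_regime not in HERBIVORE_REGIMES:
            raise ValueError(f"herbivore_regime must be one of {HERBIVORE_REGIMES}")
        if self.total_invader_inoculum <= 0 or self.resident_total_inoculum <= 0:
            raise ValueError("inocula must be > 0")
        if any(l < 1 for l in self.diversity_levels):
            raise ValueError("diversity levels must be ≥ 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be ≥ 1")
        if len(self.replicates_per_level) != len(self.diversity_levels):
            raise ValueError("replicates_per_level must match diversity_levels")
        if max(self.diversity_levels) > self.n_strains:
            raise ValueError("diversity level exceeds the strain pool")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)


@dataclass
class SimulationResult:
    """Daily trajectories of one microcosm."""

    microcosm_id: str
    days: np.ndarray  # 0..duration
    resident_biomass: pd.DataFrame  # day × species, μg ml⁻¹
    strain_biomass: pd.DataFrame  # day × strain (ground truth), μg ml⁻¹
    grazer_density: pd.Series  # day -> animals ml⁻¹

    def community_matrix(self, day: int) -> pd.Series:
        """Residents plus pooled invader biomass at one day (the microscopy
        view: invader strains are morphologically indistinguishable)."""
        row = self.resident_biomass.loc[day].copy()
        row["invader"] = self.strain_biomass.loc[day].sum()
        return row


@dataclass
class FixtureBundle:
    """Everything one synthetic experiment produced."""

    design_table: pd.DataFrame
    designs: list[MicrocosmDesign]
    census: pd.DataFrame
    strain_biomass_truth: pd.DataFrame
    marker_db: MarkerDB
    traits: dict[str, StrainTrait]
    read_paths: dict[str, Path]
    cnp_table: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Strain pool and markers
# ---------------------------------------------------------------------------


def make_traits(
    n_strains: int,
    seed: int,
    growth_rate_range: tuple[float, float] = (0.5, 1.0),
    bias_range: tuple[float, float] = (1.0, 1.0),
) -> dict[str, StrainTrait]:
    """A strain pool with a planted spread in growth rates.

    Growth rates are evenly spaced over ``growth_rate_range`` (default a
    2× spread) but assigned to strain ids in seeded random order, so strain
    identity — not label order — carries the success ranking.
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:02d}" for i in range(n_strains)]
    rates = np.linspace(*growth_rate_range, n_strains)
    rng.shuffle(rates)
    sus = rng.uniform(0.4, 1.0, n_strains)
    biases = rng.uniform(*bias_range, n_strains) if bias_range[0] != bias_range[1] \
        else np.full(n_strains, bias_range[0])
    return {
        sid: StrainTrait(sid, float(r), float(s), float(b))
        for sid, r, s, b in zip(ids, rates, sus, biases)
    }


def make_marker_db(
    strain_ids: Sequence[str],
    seed: int,
    length: int = 120,
    groups: Sequence[Sequence[str]] = (),
) -> MarkerDB:
    """Random unique marker amplicons, one per strain, seeded."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, list[str]] = {}
    used: set[str] = set()
    for sid in strain_ids:
        while True:
            s = "".join(rng.choice(bases, size=length))
            if s not in used and reverse_complement(s) not in used:
                used.add(s)
                seqs[sid] = [s]
                break
    return MarkerDB(records=seqs, groups=[frozenset(g) for g in groups])


# ---------------------------------------------------------------------------
# Community dynamics
# ---------------------------------------------------------------------------


def simulate_microcosm(
    design: MicrocosmDesign,
    traits: Mapping[str, StrainTrait],
    config: SimulationConfig,
    seed: int,
) -> SimulationResult:
    """Run the discrete-time community model for one microcosm.

    Residents grow from day 0; the invader strains are added at
    ``config.invasion_day`` at equal per-strain inoculum (total/k).  The
    grazer follows the regime's deterministic trajectory and removes
    biomass in proportion to its density and each population's
    susceptibility.  Deterministic given the seed (the seed only jitters
    resident growth rates and initial resident biomass between replicates).
    """
    unknown = [s for s in design.strain_set if s not in traits]
    if unknown:
        raise KeyError(f"strain(s) without traits: {unknown}")
    if config.total_invader_inoculum <= 0:
        raise ValueError("non-positive inoculum")

    rng = np.random.default_rng(seed)
    n_res = config.n_resident_species
    species = [f"sp{j + 1:02d}" for j in range(n_res)]
    strains = list(design.strain_set)
    k = len(strains)

    r_res = config.resident_growth_rate * rng.lognormal(
        0.0, config.resident_rate_cv, n_res
    )
    res = np.full(n_res, config.resident_total_inoculum / n_res)
    res *= rng.lognormal(0.0, config.resident_rate_cv, n_res)
    inv = np.zeros(k)
    r_inv = np.array([traits[s].growth_rate for s in strains])
    s_inv = np.array([traits[s].grazing_susceptibility for s in strains])

    g0, g_rate, pref_res, pref_inv = _REGIME_PARAMS[
        config.herbivore_regime if design.herbivore != "none" else "none"
    ]
    if design.diversity_level == 0:
        k = 0

    n_days = config.duration_days
    days = np.arange(n_days + 1)
    res_traj = np.empty((n_days + 1, n_res))
    inv_traj = np.empty((n_days + 1, max(k, 1))) if k else np.empty((n_days + 1, 0))
    graz_traj = np.empty(n_days + 1)

    grazer = g0
    for t in range(n_days + 1):
        if t == config.invasion_day and k:
            inv = np.full(k, per_strain_inoculum(config.total_invader_inoculum, k))
        res_traj[t] = res
        if k:
            inv_traj[t] = inv
        graz_traj[t] = grazer
        if t == n_days:
            break
        total = res.sum() + (inv.sum() if k else 0.0)
        crowd = 1.0 - total / config.carrying_capacity
        res = res * np.exp(
            r_res * crowd - _ATTACK_RATE * grazer * pref_res - config.dilution
        )
        if k:
            inv = inv * np.exp(
                r_inv * crowd - _ATTACK_RATE * grazer * s_inv * pref_inv
                - config.dilution
            )
        grazer = grazer * math.exp(g_rate)

    return SimulationResult(
        microcosm_id=design.microcosm_id,
        days=days,
        resident_biomass=pd.DataFrame(res_traj, index=days, columns=species),
        strain_biomass=pd.DataFrame(
            inv_traj[:, :k], index=days, columns=strains
        ),
        grazer_density=pd.Series(graz_traj, index=days, name="grazer"),
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    strain_biomass: Mapping[str, float],
    markers: MarkerDB,
    depth: int,
    seed: int,
    traits: Mapping[str, StrainTrait] | None = None,
    error_rate: float = 0.0,
    rc_probability: float = 0.5,
) -> list[str]:
    """Draw amplicon reads multinomially from the strain composition.

    Read probabilities are proportional to biomass × marker_copy_bias (bias
    1 when no traits are given).  Each read is the exact marker sequence of
    its strain, reverse-complemented with probability ``rc_probability``
    and corrupted by independent per-base substitutions at ``error_rate``.
    """
    if depth < 0:
        raise ValueError("depth must be ≥ 0")
    present = [s for s, b in strain_biomass.items() if b > 0]
    missing = [s for s in present if s not in markers.records]
    if missing:
        raise KeyError(f"strain(s) with biomass but no marker: {missing}")
    if depth == 0 or not present:
        return []
    rng = np.random.default_rng(seed)
    weights = np.array([
        strain_biomass[s] * (traits[s].marker_copy_bias if traits else 1.0)
        for s in present
    ])
    counts = rng.multinomial(depth, weights / weights.sum())
    reads: list[str] = []
    for strain, n in zip(present, counts):
        if n == 0:
            continue
        seqs = markers.records[strain]
        per_marker = rng.multinomial(n, np.full(len(seqs), 1.0 / len(seqs)))
        for seq, m in zip(seqs, per_marker):
            if m == 0:
                continue
            n_rc = rng.binomial(m, rc_probability)
            for template, count in ((seq, m - n_rc), (reverse_complement(seq), n_rc)):
                if count == 0:
                    continue
                if error_rate <= 0:
                    reads.extend([template] * count)
                    continue
                p_any = 1.0 - (1.0 - error_rate) ** len(template)
                n_err = rng.binomial(count, p_any)
                reads.extend([template] * (count - n_err))
                for _ in range(n_err):
                    reads.append(_mutate(template, error_rate, rng))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitute ≥ 1 base (conditioned on having at least one error)."""
    chars = list(seq)
    while True:
        hits = np.where(rng.random(len(chars)) < error_rate)[0]
        if hits.size:
            break
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)


def write_fastq(reads: Sequence[str], path: str | Path, sample_id: str) -> None:
    """Sanger-encoded FASTQ with uniform 'I' qualities (Q40)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{sample_id}.{i + 1}\n{read}\n+\n{'I' * len(read)}\n")


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

#: synthetic resident species morphologies (shape, d, l, w in μm); the
#: invader is a filamentous cyanobacterium-like cylinder
_RESIDENT_SHAPES = [
    ("sphere", 5.0, None, None),
    ("sphere", 2.0, None, None),
    ("cylinder", 4.0, 30.0, None),
    ("prolate_spheroid", 6.0, 12.0, None),
    ("ellipsoid", 4.0, 9.0, 3.0),
    ("double_cone", 8.0, 20.0, None),
    ("sphere", 8.0, None, None),
    ("cylinder", 2.5, 15.0, None),
]
_INVADER_SHAPE = ("cylinder", 1.8, 100.0, None)


def _shape_row(species_id: str, shape_tuple) -> dict:
    shape, d, l, w = shape_tuple
    return {"shape": shape, "dim_d_um": d, "dim_l_um": l, "dim_w_um": w}


def _species_shape(j: int):
    return _RESIDENT_SHAPES[j % len(_RESIDENT_SHAPES)]


def build_designs(config: SimulationConfig, rng: np.random.Generator,
                  strain_ids: Sequence[str]) -> list[MicrocosmDesign]:
    herb = {"none": "none", "generalist_high": "generalist",
            "generalist_low": "generalist", "specialist": "specialist"}[
        config.herbivore_regime]
    dens = _REGIME_PARAMS[config.herbivore_regime][0]
    designs = []
    idx = 0

    def add(level, chosen, rep):
        nonlocal idx
        idx += 1
        designs.append(MicrocosmDesign(
            microcosm_id=f"mc{idx:03d}",
            experiment_id="synthetic",
            diversity_level=level,
            strain_set=tuple(sorted(chosen)),
            herbivore=herb,
            herbivore_initial_density=dens,
            replicate_index=rep + 1,
        ))

    for level, n_rep in zip(config.diversity_levels, config.replicates_per_level):
        if level == 1:
            # single-strain treatments replicate EVERY strain of the pool,
            # so each strain has a monoculture yield for the substitutive null
            for strain in strain_ids:
                for rep in range(n_rep):
                    add(1, (strain,), rep)
        else:
            for rep in range(n_rep):
                chosen = rng.choice(list(strain_ids), size=level, replace=False)
                add(level, chosen, rep)
    return designs


def generate_experiment(
    config: SimulationConfig,
    out_dir: str | Path,
    traits: Mapping[str, StrainTrait] | None = None,
) -> FixtureBundle:
    """Simulate a full experiment and write it to disk.

    Emits ``design.csv``, ``census.csv`` (all sampling days, long format),
    ``markers.fasta``, per-sample FASTQ read files under ``reads/``
    (baseline = invasion day, end = last sampling day), ``cnp.csv`` and
    ``truth.csv`` (the hidden per-strain biomass ground truth).
    """
    out = Path(out_dir)
    try:
        (out / "reads").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e

    master = np.random.default_rng(config.seed)
    if traits is None:
        traits = make_traits(config.n_strains, int(master.integers(2**31)))
    else:
        master.integers(2**31)  # keep downstream seed stream stable
    strain_ids = sorted(traits)
    db = make_marker_db(strain_ids, int(master.integers(2**31)),
                        length=config.marker_length)
    designs = build_designs(config, master, strain_ids)

    sampling_days = sorted(
        min(config.invasion_day + off, config.duration_days)
        for off in config.sampling_offsets
    )
    baseline_day, end_day = sampling_days[0], sampling_days[-1]

    census_rows, truth_rows, cnp_rows = [], [], []
    read_paths: dict[str, Path] = {}
    for design in designs:
        sim_seed = int(master.integers(2**31))
        sim = simulate_microcosm(design, traits, config, sim_seed)
        for day in sampling_days:
            sample_id = f"{design.microcosm_id}_d{day}"
            comm = sim.community_matrix(day)
            for j, sp in enumerate(sim.resident_biomass.columns):
                shape = _species_shape(j)
                vol = cell_volume(ShapeSpec(sp, shape[0], {
                    k: v for k, v in zip(("d", "l", "w"), shape[1:]) if v
                }))
                census_rows.append({
                    "sample_id": sample_id, "species_id": sp,
                    "abundance_per_ml": comm[sp] / (vol * 1e-6),
                    **_shape_row(sp, shape),
                })
            if design.diversity_level > 0:
                vol = cell_volume(ShapeSpec("invader", _INVADER_SHAPE[0], {
                    k: v for k, v in zip(("d", "l", "w"), _INVADER_SHAPE[1:]) if v
                }))
                census_rows.append({
                    "sample_id": sample_id, "species_id": "invader",
                    "abundance_per_ml": comm["invader"] / (vol * 1e-6),
                    **_shape_row("invader", _INVADER_SHAPE),
                })
            for strain in design.strain_set:
                truth_rows.append({
                    "microcosm_id": design.microcosm_id, "day": day,
                    "strain": strain,
                    "biomass_ug_ml": sim.strain_biomass.loc[day, strain],
                })
            # crude elemental composition: ~20% C by fresh weight, molar
            # C:N ≈ 9, C:P ≈ 450, lognormal sample noise
            total = float(comm.sum())
            c_mass = 0.2 * total * master.lognormal(0.0, 0.05)
            cnp_rows.append({
                "sample_id": sample_id,
                "C_ug": c_mass,
                "N_ug": c_mass / 9.0 * (14.007 / 12.011) * master.lognormal(0.0, 0.05),
                "P_ug": c_mass / 450.0 * (30.974 / 12.011) * master.lognormal(0.0, 0.05),
            })
        if design.diversity_level > 0:
            for day, tp in ((baseline_day, "baseline"), (end_day, "end")):
                biom = sim.strain_biomass.loc[day].to_dict()
                reads = simulate_reads(
                    biom, db, config.read_depth, int(master.integers(2**31)),
                    traits=traits, error_rate=config.read_error_rate,
                    rc_probability=config.rc_probability,
                )
                sample = f"{design.microcosm_id}_{tp}"
                path = out / "reads" / f"{sample}.fastq"
                write_fastq(reads, path, sample)
                read_paths[sample] = path

    design_table = pd.DataFrame([
        {"microcosm_id": d.microcosm_id, "experiment_id": d.experiment_id,
         "diversity_level": d.diversity_level,
         "strains": ";".join(d.strain_set),
         "herbivore": d.herbivore,
         "herbivore_initial_density": d.herbivore_initial_density,
         "replicate_index": d.replicate_index}
        for d in designs
    ])
    census = pd.DataFrame(census_rows)
    truth = pd.DataFrame(truth_rows)
    cnp = pd.DataFrame(cnp_rows)

    paths = {
        "design": out / "design.csv",
        "census": out / "census.csv",
        "markers": out / "markers.fasta",
        "cnp": out / "cnp.csv",
        "truth": out / "truth.csv",
        "reads_dir": out / "reads",
    }
    design_table.to_csv(paths["design"], index=False)
    census.to_csv(paths["census"], index=False)
    db.to_fasta(paths["markers"])
    cnp.to_csv(paths["cnp"], index=False)
    truth.to_csv(paths["truth"], index=False)

    return FixtureBundle(
        design_table=design_table, designs=designs, census=census,
        strain_biomass_truth=truth, marker_db=db, traits=dict(traits),
        read_paths=read_paths, cnp_table=cnp, paths=paths,
    )


def load_design_table(path: str | Path) -> list[MicrocosmDesign]:
    """Read a design CSV back into MicrocosmDesign records."""
    df = pd.read_csv(path)
    designs = []
    for _, row in df.iterrows():
        strains = tuple(s for s in str(row["strains"]).split(";") if s) \
            if not pd.isna(row["strains"]) else ()
        designs.append(MicrocosmDesign(
            microcosm_id=str(row["microcosm_id"]),
            experiment_id=str(row["experiment_id"]),
            diversity_level=int(row["diversity_level"]),
            strain_set=strains,
            herbivore=str(row["herbivore"]),
            herbivore_initial_density=float(row["herbivore_initial_density"]),
            replicate_index=int(row["replicate_index"]),
        ))
    return designs
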
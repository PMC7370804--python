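"""End-to-end orchestration: generate → demux → biovolume → stats → ordination.

A single YAML config drives a full run.  ``validate_inputs`` checks file
existence, FASTA/FASTQ well-formedness, CSV schemas and design/marker
cross-references, collecting every failure rather than stopping at the
first.  ``run_pipeline`` executes the stages in dependency order and writes
a manifest recording the package version, seeds and input digests, so a
re-run with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biovolume import census_to_biomass, cnp_table
from .demux import (
    BASELINE,
    END,
    MarkerDB,
    collapse_groups,
    design_labels,
    exclude_undetected,
    gainloss_to_frame,
    load_reads,
    match_reads,
    relative_shares,
    shares_to_frame,
    strain_gain_loss,
)
from .ordination import strain_effect_test, bray_curtis, pca
from .stats import (
    coefficient_of_variation,
    diversity_effect,
    expected_yield,
    invasion_yield,
    strain_success_summary,
)
from .synthetic import SimulationConfig, generate_experiment, load_design_table

logger = logging.getLogger(__name__)

_CENSUS_COLUMNS = {"sample_id", "species_id", "abundance_per_ml", "shape"}
_DESIGN_COLUMNS = {"microcosm_id", "experiment_id", "diversity_level", "strains",
                   "herbivore", "herbivore_initial_density", "replicate_index"}
_CNP_COLUMNS = {"sample_id", "C_ug", "N_ug", "P_ug"}


@dataclass
class PipelineConfig:
    """Paths, seeds and per-module options for one pipeline run."""

    markers: Path
    design: Path
    reads_dir: Path
    census: Path
    out_dir: Path
    cnp: Path | None = None
    seed: int = 0
    n_perm: int = 10_000
    ci_level: float = 0.95
    allow_rc: bool = True
    yield_metric: str = "share"  # or "biomass"
    generator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("markers", "design", "reads_dir", "census", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.cnp is not None:
            self.cnp = Path(self.cnp)
        if self.n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        if self.yield_metric not in ("share", "biomass"):
            raise ValueError("yield_metric must be 'share' or 'biomass'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_fastq(path: Path, failures: list[str]) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        failures.append(
            f"{path}: truncated FASTQ record starting at line "
            f"{(len(lines) // 4) * 4 + 1}"
        )
        return
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@"):
            failures.append(f"{path}: malformed header at line {i + 1}")
            return
        if not lines[i + 2].startswith("+"):
            failures.append(f"{path}: malformed separator at line {i + 3}")
            return
        if len(lines[i + 1]) != len(lines[i + 3]):
            failures.append(
                f"{path}: sequence/quality length mismatch at line {i + 2}"
            )
            return


def _check_csv(path: Path, required: set[str], failures: list[str]) -> None:
    try:
        head = pd.read_csv(path, nrows=0)
    except Exception as e:  # noqa: BLE001 - report, do not crash validation
        failures.append(f"{path}: unreadable CSV ({e})")
        return
    missing = required - set(head.columns)
    if missing:
        failures.append(f"{path}: missing column(s) {sorted(missing)}")


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Return the full list of validation failures (empty = valid)."""
    failures: list[str] = []
    for name in ("markers", "design", "census"):
        p = getattr(config, name)
        if not p.exists():
            failures.append(f"{name} file not found: {p}")
    if not config.reads_dir.is_dir():
        failures.append(f"reads directory not found: {config.reads_dir}")
    if config.cnp is not None and not config.cnp.exists():
        failures.append(f"cnp file not found: {config.cnp}")
    if failures:
        return failures

    db = None
    try:
        db = MarkerDB.from_fasta(config.markers)
    except Exception as e:  # noqa: BLE001
        failures.append(f"{config.markers}: invalid marker FASTA ({e})")

    _check_csv(config.design, _DESIGN_COLUMNS, failures)
    _check_csv(config.census, _CENSUS_COLUMNS, failures)
    if config.cnp is not None:
        _check_csv(config.cnp, _CNP_COLUMNS, failures)

    if db is not None and config.design.exists():
        try:
            designs = load_design_table(config.design)
        except Exception as e:  # noqa: BLE001
            designs = []
            failures.append(f"{config.design}: unreadable design table ({e})")
        known = set(db.records)
        for d in designs:
            unknown = [s for s in d.strain_set if s not in known]
            if unknown:
                failures.append(
                    f"design {d.microcosm_id}: strain(s) {unknown} absent "
                    f"from marker database"
                )

    for fq in sorted(config.reads_dir.glob("*.fastq")):
        _check_fastq(fq, failures)
    return failures


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all analysis stages; returns the manifest dict.

    Stage order: demultiplex reads per sample → shares, gain/loss and
    exclusions; census → biomass and community shares (and C:N:P if
    provided); invasion-yield statistics per diversity level; strain
    success summaries with rank consistency; resident-community PERMANOVA
    and PCA over the single-strain microcosms at the end timepoint.
    """
    failures = validate_inputs(config)
    if failures:
        raise ValueError("validation failed:\n" + "\n".join(failures))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    db = MarkerDB.from_fasta(config.markers)
    designs = load_design_table(config.design)
    by_id = {d.microcosm_id: d for d in designs}

    stage = "demux"
    try:
        share_tables = {}
        all_counts, gainloss, exclusions = [], [], []
        for d in designs:
            if d.diversity_level == 0:
                continue
            labels = design_labels(d.strain_set, db)
            tables = {}
            for tp in (BASELINE, END):
                path = config.reads_dir / f"{d.microcosm_id}_{tp}.fastq"
                if not path.exists():
                    logger.warning("%s: no %s reads, timepoint unmatched",
                                   d.microcosm_id, tp)
                    continue
                reads = load_reads(path)
                counts = match_reads(reads, db, sample_id=f"{d.microcosm_id}_{tp}",
                                     allow_rc=config.allow_rc,
                                     design_strains=set(d.strain_set))
                counts = collapse_groups(counts, set(d.strain_set), db)
                all_counts.append(counts)
                tables[tp] = relative_shares(counts, tp, labels=labels)
            share_tables[d.microcosm_id] = tables
            if BASELINE in tables:
                excl, reason = exclude_undetected(d.strain_set, tables[BASELINE], db)
                if excl:
                    exclusions.append(
                        {"microcosm_id": d.microcosm_id, "reason": reason}
                    )
                    continue
            if BASELINE in tables and END in tables:
                gainloss.append(
                    strain_gain_loss(tables[BASELINE], tables[END],
                                     mixture_id=d.microcosm_id)
                )
        shares_frame = shares_to_frame(
            [t for tabs in share_tables.values() for t in tabs.values()]
        )
        shares_frame.to_csv(out / "shares.csv", index=False)
        from .demux import counts_to_frame
        counts_to_frame(all_counts).to_csv(out / "counts.csv", index=False)
        gainloss_to_frame(gainloss).to_csv(out / "gainloss.csv", index=False)
        pd.DataFrame(exclusions, columns=["microcosm_id", "reason"]).to_csv(
            out / "exclusions.csv", index=False
        )

        stage = "biovolume"
        census = pd.read_csv(config.census)
        biomass_df = census_to_biomass(census)
        biomass_df.to_csv(out / "biomass.csv", index=False)
        if config.cnp is not None:
            cnp_table(pd.read_csv(config.cnp)).to_csv(
                out / "cnp_ratios.csv", index=False
            )

        stage = "invasion_stats"
        stats_report = _invasion_statistics(
            config, designs, biomass_df, share_tables, gainloss,
            {e["microcosm_id"] for e in exclusions}, out,
        )

        stage = "ordination"
        ordination_report = _ordination(config, designs, biomass_df, out)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    input_digests = {
        name: _sha256(getattr(config, name))
        for name in ("markers", "design", "census")
    }
    # run id hashes inputs and analysis options, not paths, so the same
    # analysis of the same data gets the same id wherever it is written
    run_key = {
        "inputs": input_digests, "seed": config.seed, "n_perm": config.n_perm,
        "ci_level": config.ci_level, "allow_rc": config.allow_rc,
        "yield_metric": config.yield_metric,
    }
    manifest = {
        "run_id": hashlib.sha256(
            json.dumps(run_key, sort_keys=True).encode()
        ).hexdigest()[:16],
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "inputs": input_digests,
        "n_excluded_mixtures": len(exclusions),
        "stats": stats_report,
        "ordination": ordination_report,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _endpoint_invader_yield(biomass_df: pd.DataFrame, sample_id: str,
                            metric: str) -> float | None:
    sub = biomass_df[biomass_df["sample_id"] == sample_id]
    if sub.empty:
        return None
    inv = sub[sub["species_id"] == "invader"]
    if inv.empty:
        return 0.0
    col = "share" if metric == "share" else "biomass_ug_ml"
    return float(inv[col].iloc[0])


def _end_sample_of(designs, biomass_df) -> dict[str, str]:
    """microcosm -> last sampling-day census sample id."""
    days: dict[str, int] = {}
    for sid in biomass_df["sample_id"].unique():
        base, _, d = str(sid).rpartition("_d")
        try:
            day = int(d)
        except ValueError:
            continue
        if base not in days or day > days[base]:
            days[base] = day
    return {m: f"{m}_d{d}" for m, d in days.items()}


def _invasion_statistics(config, designs, biomass_df, share_tables,
                         gainloss, excluded_ids, out: Path) -> dict:
    end_sample = _end_sample_of(designs, biomass_df)
    singles: dict[str, list[float]] = {}
    mix_obs: dict[str, float] = {}
    for d in designs:
        if d.microcosm_id in excluded_ids or d.microcosm_id not in end_sample:
            continue
        y = _endpoint_invader_yield(
            biomass_df, end_sample[d.microcosm_id], config.yield_metric
        )
        if y is None:
            continue
        if d.diversity_level == 1:
            singles.setdefault(d.strain_set[0], []).append(y)
        elif d.diversity_level > 1:
            mix_obs[d.microcosm_id] = y

    single_means = {s: float(np.mean(v)) for s, v in singles.items()}
    yields_by_level: dict[int, list[float]] = {}
    n_skipped = 0
    for d in designs:
        if d.microcosm_id not in mix_obs:
            continue
        try:
            exp = expected_yield(d.strain_set, single_means)
        except KeyError:
            n_skipped += 1
            continue
        yields_by_level.setdefault(d.diversity_level, []).append(
            invasion_yield(mix_obs[d.microcosm_id], exp)
        )
    results = diversity_effect(yields_by_level, ci_level=config.ci_level)
    pd.DataFrame([vars(r) for r in results]).to_csv(
        out / "invasion_yield.csv", index=False
    )

    # endpoint in-mixture shares per strain from the demux share tables
    mixture_shares: dict[str, list[float]] = {}
    for d in designs:
        if d.diversity_level <= 1 or d.microcosm_id in excluded_ids:
            continue
        tabs = share_tables.get(d.microcosm_id, {})
        if END not in tabs or tabs[END].undefined:
            continue
        for strain, share in tabs[END].shares.items():
            mixture_shares.setdefault(strain, []).append(share)

    report: dict = {"n_mixtures_skipped_no_single": n_skipped}
    cv_in = [v for vs in singles.values() for v in vs]
    if len(cv_in) >= 2 and np.mean(cv_in) != 0:
        report["cv_single_strain_yield"] = coefficient_of_variation(cv_in)
    try:
        summaries, consistency = strain_success_summary(
            mixture_shares, singles, gainloss
        )
        pd.DataFrame([vars(s) for s in summaries]).to_csv(
            out / "strain_summary.csv", index=False
        )
        report["consistency"] = consistency
    except ValueError as e:
        logger.warning("strain consistency not computable: %s", e)
    with open(out / "correlations.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def _ordination(config, designs, biomass_df, out: Path) -> dict:
    end_sample = _end_sample_of(designs, biomass_df)
    singles = [d for d in designs
               if d.diversity_level == 1 and d.microcosm_id in end_sample]
    strains = {d.strain_set[0] for d in singles}
    if len(strains) < 2 or len(singles) < 3:
        logger.warning("too few single-strain microcosms for ordination")
        return {"skipped": True}
    wide = biomass_df.pivot_table(index="sample_id", columns="species_id",
                                  values="biomass_ug_ml", fill_value=0.0)
    rows = [end_sample[d.microcosm_id] for d in singles]
    community = wide.loc[rows]
    community.index = [d.microcosm_id for d in singles]
    result = strain_effect_test(community, singles, n_perm=config.n_perm,
                                seed=config.seed)
    res = result["permanova"]
    residents = community.drop(columns=["invader"], errors="ignore")
    bray_curtis(residents).to_csv(out / "distance_matrix.csv")
    p = pca(residents)
    pd.DataFrame(p.scores, index=residents.index,
                 columns=[f"PC{i+1}" for i in range(p.scores.shape[1])]
                 ).to_csv(out / "pca_scores.csv")
    pd.DataFrame(p.loadings, index=residents.columns,
                 columns=[f"PC{i+1}" for i in range(p.loadings.shape[1])]
                 ).to_csv(out / "pca_loadings.csv")
    report = {
        "pseudo_F": res.pseudo_F, "R2": res.R2, "p_value": res.p_value,
        "n_permutations": res.n_permutations, "seed": res.seed,
        "method": res.method,
        "mean_within_strain_distance": result["mean_within_strain_distance"],
        "mean_between_strain_distance": result["mean_between_strain_distance"],
        "pca_variance_explained": [float(v) for v in p.explained_variance_ratio],
    }
    with open(out / "permanova.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def invasion_stats_from_files(
    design: str | Path,
    biomass_csv: str | Path,
    shares_csv: str | Path,
    gainloss_csv: str | Path,
    out_dir: str | Path,
    yield_metric: str = "share",
    ci_level: float = 0.95,
) -> dict:
    """Standalone invasion statistics from previously written stage outputs.

    Reconstructs the share and gain/loss tables from the demux CSVs, takes
    observed yields from the biovolume output and writes the same result
    files as the full pipeline's statistics stage.
    """
    from .demux import GainLossTable, ShareTable

    designs = load_design_table(design)
    biomass_df = pd.read_csv(biomass_csv)
    shares = pd.read_csv(shares_csv)
    gl = pd.read_csv(gainloss_csv)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    share_tables: dict[str, dict[str, ShareTable]] = {}
    for (sid, tp), grp in shares.dropna(subset=["strain"]).groupby(
        ["sample_id", "timepoint"]
    ):
        micro = str(sid).rsplit("_", 1)[0]
        share_tables.setdefault(micro, {})[tp] = ShareTable(
            str(sid), tp, dict(zip(grp["strain"], grp["share"]))
        )
    gainloss = []
    for mid, grp in gl.groupby("mixture_id"):
        if grp["excluded"].any():
            gainloss.append(GainLossTable(str(mid), {}, excluded=True,
                                          reason=str(grp["reason"].iloc[0])))
            continue
        gainloss.append(GainLossTable(
            str(mid), dict(zip(grp["strain"], grp["delta_share"])),
            dominant=set(grp.loc[grp["dominant"], "strain"]),
        ))
    excluded = {t.mixture_id for t in gainloss if t.excluded}

    class _Opts:
        pass

    opts = _Opts()
    opts.yield_metric = yield_metric
    opts.ci_level = ci_level
    return _invasion_statistics(opts, designs, biomass_df, share_tables,
                                [t for t in gainloss if not t.excluded],
                                excluded, out)


def generate(config_path: str | Path) -> Path:
    """Generate a synthetic experiment from a YAML config; returns its directory."""
    with open(config_path) as fh:
        data = yaml.safe_load(fh) or {}
    out_dir = Path(data.pop("out_dir", "synthetic_experiment"))
    sim = SimulationConfig(**data)
    generate_experiment(sim, out_dir)
    return out_dir
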
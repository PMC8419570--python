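"""End-to-end orchestration: config, I/O round-trips, the full analysis run.

A run goes: audio ingestion (or synthesis) -> preprocessing -> the nine
features -> species means -> per-feature / mean acoustic distance matrices
-> genetic distances (alignment p-distance and ensemble-mean cophenetic) ->
closest-relative test, per-species correlations, Mantel tests, body-mass
regressions -> Blomberg's K and Pagel's lambda over the tree ensemble.
Every output table is written as CSV and listed, with a checksum, in a JSON
run report that also records the config hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import distances as dist
from . import features as feat
from . import stats as st
from . import synthetic as syn
from .exceptions import LabelAlignmentError, PhylosongError
from .phylosignal import ensemble_signal

logger = logging.getLogger(__name__)

__version__ = "0.1.0"
CONFIG_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisParams:
    n_perm_mantel: int = 5000
    n_perm_k: int = 1000
    fft: int = feat.DEFAULT_FFT
    hop: int = feat.DEFAULT_HOP
    sr: int = feat.DEFAULT_SR
    bandpass_low_hz: float = 100.0
    bandpass_high_hz: float = 10000.0


@dataclass(frozen=True)
class RealInputs:
    audio_dir: str
    trees: str
    alignment: str
    masses: str


@dataclass(frozen=True)
class StudyConfig:
    """Exactly one of ``real``/``synthetic`` plus analysis params and a seed."""

    seed: int = 0
    real: RealInputs | None = None
    synthetic: syn.StudyDesign | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self):
        if (self.real is None) == (self.synthetic is None):
            raise ValueError(
                "config must provide exactly one of a 'real' or 'synthetic' block"
            )

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "params": dataclasses.asdict(self.params),
             "schema_version": CONFIG_SCHEMA_VERSION}
        if self.real is not None:
            d["real"] = dataclasses.asdict(self.real)
        if self.synthetic is not None:
            sy = dataclasses.asdict(self.synthetic)
            sy["duration_range"] = list(sy["duration_range"])
            d["synthetic"] = sy
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    real = RealInputs(**raw["real"]) if "real" in raw else None
    synthetic = None
    if "synthetic" in raw:
        sy = dict(raw["synthetic"])
        if "duration_range" in sy:
            sy["duration_range"] = tuple(sy["duration_range"])
        synthetic = syn.StudyDesign(**sy)
    params = AnalysisParams(**raw.get("params", {}))
    return StudyConfig(
        seed=int(raw.get("seed", 0)), real=real, synthetic=synthetic, params=params
    )


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------

def read_trees(path) -> list:
    """Read a multi-tree Newick file (one tree per line allowed)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if not trees:
        raise PhylosongError(f"no trees found in {path}")
    return list(trees)


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def read_fasta_alignment(path) -> dict:
    """Read an aligned FASTA into {id: sequence}; lengths must agree."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PhylosongError(f"no sequences found in {path}")
    out = {}
    for rec in records:
        if rec.id in out:
            raise PhylosongError(f"duplicate sequence ID {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        by_len = sorted(out, key=lambda k: len(out[k]))
        raise PhylosongError(
            f"alignment lengths differ in {path}: e.g. {by_len[0]!r} "
            f"({len(out[by_len[0]])}) vs {by_len[-1]!r} ({len(out[by_len[-1]])})"
        )
    return out


def write_fasta_alignment(alignment: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


def read_body_masses(path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PhylosongError(f"body-mass CSV {path} needs id and mass columns")
    s = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    s.name = "body_mass_g"
    return s


def ingest_audio_dir(audio_dir, params: AnalysisParams) -> dict:
    """Read ``<species>__<idx>.wav`` files, preprocess, group by species."""
    audio_dir = Path(audio_dir)
    wavs = sorted(audio_dir.glob("*.wav"))
    if not wavs:
        raise PhylosongError(f"no .wav files in {audio_dir}")
    grouped = {}
    for path in wavs:
        stem = path.stem
        if "__" not in stem:
            raise PhylosongError(
                f"audio file {path.name} does not follow '<species>__<idx>.wav'"
            )
        species = stem.split("__")[0]
        w = feat.preprocess(
            feat.read_wav(path),
            low_hz=params.bandpass_low_hz,
            high_hz=params.bandpass_high_hz,
            target_sr=params.sr,
        )
        grouped.setdefault(species, []).append((stem, w))
    return grouped


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}

    def add_output(self, name: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _check_species_consistency(**label_sets) -> None:
    names = list(label_sets)
    ref_name = names[0]
    ref = set(label_sets[ref_name])
    problems = []
    for name in names[1:]:
        s = set(label_sets[name])
        only_ref = sorted(ref - s)
        only_s = sorted(s - ref)
        if only_ref or only_s:
            problems.append(
                f"{ref_name} vs {name}: only in {ref_name}: {only_ref}; "
                f"only in {name}: {only_s}"
            )
    if problems:
        raise LabelAlignmentError(
            "species sets are inconsistent across inputs:\n" + "\n".join(problems)
        )


def run_pipeline(cfg: StudyConfig, out_dir, force: bool = False) -> RunReport:
    """Run the full analysis and write all result CSVs plus a JSON report.

    With ``force=False`` a run whose report exists with the same config hash
    is skipped and the existing report returned.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "run_report.json"
    cfg_hash = cfg.hash()
    if report_path.exists() and not force:
        prev = json.loads(report_path.read_text())
        if prev.get("config_hash") == cfg_hash:
            logger.info("cached run with matching config hash; use force=True to redo")
            return RunReport(**prev)

    report = RunReport(config_hash=cfg_hash, seed=cfg.seed, version=__version__)
    t_start = time.time()

    def stage(name):
        report.stages.append({"stage": name, "t": round(time.time() - t_start, 3)})
        logger.info("stage: %s", name)

    # --- inputs -----------------------------------------------------------
    stage("inputs")
    if cfg.synthetic is not None:
        study = syn.generate_study(cfg.synthetic, seed=cfg.seed)
        syn.write_study(study, out / "study")
        grouped = {
            sp: [
                (f"{sp}__{j}", feat.preprocess(
                    w, cfg.params.bandpass_low_hz, cfg.params.bandpass_high_hz,
                    cfg.params.sr,
                ))
                for j, w in enumerate(recs)
            ]
            for sp, recs in study.recordings.items()
        }
        trees = study.ensemble
        alignment = study.alignment
        masses = study.body_masses
    else:
        grouped = ingest_audio_dir(cfg.real.audio_dir, cfg.params)
        trees = read_trees(cfg.real.trees)
        alignment = read_fasta_alignment(cfg.real.alignment)
        masses = read_body_masses(cfg.real.masses)

    tip_labels = sorted(leaf.taxon.label for leaf in trees[0].leaf_node_iter())
    _check_species_consistency(
        audio=grouped.keys(), tree=tip_labels, alignment=alignment.keys(),
        masses=masses.index,
    )

    # --- features ---------------------------------------------------------
    stage("features")
    per_rec_rows = {}
    by_species = {}
    for sp, recs in grouped.items():
        vecs = []
        for rec_id, w in recs:
            fv = feat.extract_feature_vector(
                w, fft=cfg.params.fft, hop=cfg.params.hop, recording_id=rec_id
            )
            per_rec_rows[rec_id] = fv.to_dict() | {"species_id": sp}
            vecs.append(fv)
        by_species[sp] = vecs
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        table = feat.aggregate_species_means(by_species)
    for wmsg in caught:
        report.warnings.append(str(wmsg.message))
    per_rec = pd.DataFrame.from_dict(per_rec_rows, orient="index").rename_axis(
        "recording_id"
    )
    per_rec_path = out / "features_per_recording.csv"
    per_rec.to_csv(per_rec_path)
    report.add_output("features_per_recording", per_rec_path)
    table_path = out / "features_species.csv"
    table.to_csv(table_path)
    report.add_output("features_species", table_path)

    # --- distance matrices ------------------------------------------------
    stage("distances")
    feature_mats = {}
    for name in feat.FEATURE_NAMES:
        D = dist.normalize_distance_matrix(dist.feature_distance_matrix(table, name))
        feature_mats[name] = D
        p = out / f"dist_{name}.csv"
        D.to_csv(p)
        report.add_output(f"dist_{name}", p)
    mean_acoustic = dist.mean_acoustic_distance(list(feature_mats.values()))
    p = out / "dist_mean_acoustic.csv"
    mean_acoustic.to_csv(p)
    report.add_output("dist_mean_acoustic", p)

    Dg_tree = dist.ensemble_mean_matrix(trees)
    p = out / "dist_genetic_tree.csv"
    Dg_tree.to_csv(p)
    report.add_output("dist_genetic_tree", p)
    Dg_seq = dist.p_distance_matrix(alignment)
    p = out / "dist_genetic_pdistance.csv"
    Dg_seq.to_csv(p)
    report.add_output("dist_genetic_pdistance", p)

    # --- matrix statistics -------------------------------------------------
    stage("stats")
    mantel_rows = []
    for name, D in [*feature_mats.items(), ("mean_acoustic", mean_acoustic)]:
        res = st.mantel_test(
            Dg_tree, D, n_perm=cfg.params.n_perm_mantel,
            seed=syn.derive_seed(cfg.seed, "mantel", name),
        )
        mantel_rows.append({"measure": name, "r": res.r, "p": res.p,
                            "n_perm": res.n_perm})
    mass_mat = _log_mass_distance_matrix(masses, Dg_tree.labels)
    res = st.mantel_test(
        Dg_tree, mass_mat, n_perm=cfg.params.n_perm_mantel,
        seed=syn.derive_seed(cfg.seed, "mantel", "body_mass"),
    )
    mantel_rows.append({"measure": "body_mass", "r": res.r, "p": res.p,
                        "n_perm": res.n_perm})
    mantel_df = pd.DataFrame(mantel_rows)
    p = out / "mantel.csv"
    mantel_df.to_csv(p, index=False)
    report.add_output("mantel", p)

    crt = st.closest_relative_test(Dg_tree, mean_acoustic)
    p = out / "closest_relative.csv"
    pd.DataFrame(
        [{"t": crt.statistic, "df": crt.df, "p": crt.p}]
    ).to_csv(p, index=False)
    report.add_output("closest_relative", p)

    corr = st.species_mean_correlations(Dg_tree, feature_mats)
    p = out / "species_correlations.csv"
    corr_df = corr.per_species_by_feature.copy()
    corr_df["mean_r"] = corr.per_species_r
    corr_df.rename_axis("species_id").to_csv(p)
    report.add_output("species_correlations", p)

    n_predictors = len(feature_mats) + 1
    if Dg_tree.n - 1 >= n_predictors + 2:
        reg = st.species_regressions(Dg_tree, feature_mats, masses)
        p = out / "regression_betas.csv"
        reg.per_species_beta.rename_axis("species_id").to_csv(p)
        report.add_output("regression_betas", p)
        p = out / "regression_summary.csv"
        pd.DataFrame(
            {"mean_beta": reg.mean_beta, "sd_beta": reg.sd_beta}
        ).rename_axis("predictor").to_csv(p)
        report.add_output("regression_summary", p)
    else:
        msg = (
            f"too few species ({Dg_tree.n}) for the {n_predictors}-predictor "
            "regressions; stage skipped"
        )
        logger.warning(msg)
        report.warnings.append(msg)

    # --- phylogenetic signal ------------------------------------------------
    stage("phylosignal")
    sig = ensemble_signal(
        trees, table, n_perm=cfg.params.n_perm_k, seed=cfg.seed
    )
    p = out / "signal_per_tree.csv"
    sig.per_tree.to_csv(p, index=False)
    report.add_output("signal_per_tree", p)
    p = out / "signal_summary.csv"
    sig.summary.rename_axis("feature").to_csv(p)
    report.add_output("signal_summary", p)

    stage("done")
    report_path.write_text(report.to_json())
    return report


def _log_mass_distance_matrix(masses: pd.Series, labels) -> dist.DistanceMatrix:
    logm = np.log(masses[list(labels)].to_numpy(dtype=float))
    return dist.DistanceMatrix(labels, np.abs(logm[:, None] - logm[None, :]))
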
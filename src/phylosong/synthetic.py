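"""Synthetic study generator: trees, traits, sequences, masses, vocalizations.

The real analysis needs WAV recordings, a bootstrapped tree ensemble, an
aligned marker gene and body masses. This module generates all of them with
the statistical structure the analysis assumes, so every downstream stage is
testable offline and with known ground truth:

* an ultrametric pure-birth (Yule) tree scaled to unit root-to-tip depth;
* a bootstrap-like ensemble made by multiplying every branch length by an
  independent log-normal factor (median 1);
* per-species latent traits evolved as Brownian motion with Pagel's lambda
  scaling the off-diagonal covariance — these latents drive the synthesized
  audio, so the measured acoustic features inherit the phylogenetic signal;
* gapless aligned sequences evolved site-independently under Jukes-Cantor;
* log-normal body masses from one extra Brownian latent (log-mass), which
  couples mass differences to genetic distance;
* vocalizations built from a harmonic stack plus band-passed noise, with
  monotone mappings from the latent traits to carrier frequency, harmonic/
  noise mix, amplitude-modulation depth, frequency-sweep rate and per-band
  tonal gains.

Everything is deterministic given the master seed; per-species and
per-recording seeds are derived by stable hashing so outputs do not depend
on generation order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import LabelAlignmentError
from .features import Waveform, write_wav
from .phylosignal import phylo_vcv

logger = logging.getLogger(__name__)

#: latent traits driving the synthesizer, in fixed order
LATENT_TRAITS = (
    "centroid",
    "tonality",
    "amp_mod",
    "sweep",
    "band1",
    "band2",
    "band3",
    "band4",
)

#: STFT bin width (Hz) of the default analysis grid (sr 22050, fft 512);
#: band tones sit on bin centres so their energy stays in-bin
_BIN_HZ = 22050.0 / 512.0

#: per-band tonal components, as STFT bin indices inside each contrast band
_BAND_TONE_BINS = {
    "band1": (5, 7, 10),      # 215, 301, 431 Hz   (band 0-500)
    "band2": (13, 16, 20),    # 560, 689, 861 Hz   (band 500-1000)
    "band3": (26, 31, 42),    # 1120, 1335, 1809 Hz (band 1000-2000)
    "band4": (50, 62, 85),    # 2153, 2670, 3661 Hz (band 2000-4000)
}


def derive_seed(master: int, *parts) -> int:
    """Stable 31-bit seed from a master seed and hashable parts."""
    key = "|".join([str(master), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (
        2**31
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with unit root-to-tip depth.

    Lineages split at exponential waiting times (rate = k * birth_rate for k
    extant lineages); after reaching ``n_tips`` a final waiting time extends
    all pendant edges, and the whole tree is rescaled so every tip is at
    depth 1. Tips are labelled sp001, sp002, ...
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0
    left = dendropy.Node(edge_length=0.0)
    right = dendropy.Node(edge_length=0.0)
    root.add_child(left)
    root.add_child(right)
    active = [left, right]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        c1 = dendropy.Node(edge_length=0.0)
        c2 = dendropy.Node(edge_length=0.0)
        parent.add_child(c1)
        parent.add_child(c2)
        active.extend([c1, c2])
    final = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += final
    width = len(str(n_tips))
    for i, node in enumerate(active, start=1):
        node.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    # rescale to unit depth (tree is ultrametric by construction)
    depth = 0.0
    node = active[0]
    while node is not root:
        depth += node.edge.length
        node = node.parent_node
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    tree.is_rooted = True
    return tree


def jitter_ensemble(
    tree: dendropy.Tree, n_trees: int, jitter_sd: float, seed: int = 0
) -> list:
    """Bootstrap-like ensemble: per-branch multiplicative log-normal jitter.

    Each output tree keeps the input topology; every branch length is
    multiplied by an independent log-normal factor with median 1 and log-sd
    ``jitter_sd``, emulating bootstrap variation in branch-length estimates.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree in the ensemble")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        t = tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length:
                edge.length = float(
                    edge.length * np.exp(rng.normal(0.0, jitter_sd))
                )
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# traits and sequences
# ---------------------------------------------------------------------------

def simulate_lambda_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lam: float = 1.0,
    trait_names=LATENT_TRAITS,
    seed: int = 0,
    root_value: float = 0.0,
) -> pd.DataFrame:
    """Tip traits from Brownian motion with lambda-scaled covariance.

    Each trait is an independent draw from MVN(root_value, sigma2 * V(lam)),
    where V is the phylogenetic VCV of the tree and V(lam) multiplies its
    off-diagonal entries by lam. Returns a DataFrame indexed by species.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    vcv = phylo_vcv(tree)
    V = vcv.values * lam
    np.fill_diagonal(V, np.diag(vcv.values))
    rng = np.random.default_rng(seed)
    n = vcv.n
    if sigma2 == 0:
        values = np.full((n, len(trait_names)), root_value)
    else:
        # tiny jitter keeps the Cholesky stable for lam = 1 on deep trees
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
        values = root_value + L @ rng.standard_normal((n, len(trait_names)))
    return pd.DataFrame(values, index=list(vcv.labels), columns=list(trait_names))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_jc_alignment(
    tree: dendropy.Tree, n_sites: int = 1000, seed: int = 0
) -> dict:
    """Gapless aligned sequences evolved under the Jukes-Cantor model.

    Branch lengths are expected substitutions per site. Along a branch of
    length t each site is independently redrawn uniformly from {A,C,G,T}
    with probability 1 - exp(-4t/3), which yields the JC69 transition
    P(i -> j != i) = (1 - exp(-4t/3))/4. Returns {species: sequence}.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    seqs = {root: _BASES[rng.integers(4, size=n_sites)]}
    out = {}
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[node]
        else:
            t = node.edge.length or 0.0
            parent_seq = seqs[node.parent_node]
            p_redraw = 1.0 - np.exp(-4.0 * t / 3.0)
            redraw = rng.random(n_sites) < p_redraw
            seq = parent_seq.copy()
            seq[redraw] = _BASES[rng.integers(4, size=int(redraw.sum()))]
            seqs[node] = seq
        if node.is_leaf():
            out[node.taxon.label] = seqs[node].tobytes().decode("ascii")
    for node in list(seqs):  # free internal sequences
        if not node.is_leaf():
            del seqs[node]
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# vocal synthesis
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def synthesize_vocalization(
    traits,
    duration_s: float = 1.0,
    sr: int = 22050,
    seed: int = 0,
    n_harmonics: int = 10,
) -> Waveform:
    """Parametric vocalization whose measured features track the latents.

    ``traits`` maps latent names (see LATENT_TRAITS; missing latents default
    to 0) to real values on roughly unit scale. With u = sigmoid(latent),
    the monotone control mappings are:

    * centroid -> carrier frequency of a harmonic stack, 300-8000 Hz
      (linear in u, so the baseline carrier sits above the contrast bands);
    * tonality -> harmonic vs band-passed-noise mix (u -> 1 = pure harmonic);
    * amp_mod  -> sinusoidal amplitude-modulation depth in [0, 1] at 6 Hz;
    * sweep    -> prominence of a frequency-warbling component (a tone
      jumping +/-0.35 octaves around 1.3x the carrier at 8 jumps/s); each
      jump renews the spectrum, so per-frame spectral flux spikes grow with
      this component's amplitude;
    * band1..band4 -> amplitude of three bin-centred tones inside the band.

    Rank information on every latent survives the extraction round-trip;
    the spectral-flux dial drives the energy of the frequency-modulated
    component rather than a raw sweep rate, because flux responds to how
    much of the spectrum moves per frame, not to how far it moves.
    """
    if not 0.2 <= duration_s <= 8.0:
        raise ValueError("duration must lie in [0.2, 8] s")
    if not 8000 <= sr <= 96000:
        raise ValueError("sample rate must lie in [8000, 96000]")
    tr = dict(traits) if not isinstance(traits, pd.Series) else traits.to_dict()
    get = lambda k: float(tr.get(k, 0.0))
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sr))
    t = np.arange(n) / sr

    u_c = _sigmoid(get("centroid"))
    f0 = 300.0 + 7700.0 * u_c
    phase = 2 * np.pi * f0 * t
    harmonic = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        if k * f0 >= 0.45 * sr:
            break
        harmonic += np.sin(k * phase + rng.uniform(0, 2 * np.pi)) / k
    if harmonic.std() > 0:
        harmonic /= harmonic.std()

    noise = rng.standard_normal(n)
    sos = scipy.signal.butter(4, [100.0, min(10000.0, 0.45 * sr)],
                              btype="bandpass", fs=sr, output="sos")
    noise = scipy.signal.sosfiltfilt(sos, noise)
    noise /= noise.std()

    h = _sigmoid(get("tonality"))
    x = h * harmonic + (1.0 - h) * noise

    # warble: frequency-jumping tone near the carrier; amplitude is the
    # spectral-flux dial
    a_w = 3.5 * _sigmoid(get("sweep"))
    seg = np.floor(8.0 * t).astype(int)
    jump = np.where(seg % 2 == 0, 0.35, -0.35)
    f_w = min(1.3 * f0, 7000.0) * 2.0 ** jump
    x = x + a_w * np.sin(2 * np.pi * np.cumsum(f_w) / sr + rng.uniform(0, 2 * np.pi))

    # three bin-centred tones per contrast band (added pre-AM so the
    # modulation envelope covers them too)
    for name, bins in _BAND_TONE_BINS.items():
        amp = _sigmoid(get(name)) / np.sqrt(3.0)
        for b in bins:
            x = x + amp * np.sin(2 * np.pi * b * _BIN_HZ * t + rng.uniform(0, 2 * np.pi))

    depth = _sigmoid(get("amp_mod"))
    x = x * (1.0 - depth * (0.5 - 0.5 * np.cos(2 * np.pi * 6.0 * t)))

    x = x + 0.01 * rng.standard_normal(n)  # noise floor so valleys exist
    x = 0.9 * x / np.max(np.abs(x))
    return Waveform(x, sr)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a synthetic study (the study conditions).

    Defaults follow the emulated study design: 2-6 vocalizations per
    species, a 100-tree bootstrap ensemble, ~1000-bp alignment, recordings
    of 0.5-3 s at 22 050 Hz; within-species latent noise sd is 10% of the
    between-species Brownian sd.
    """

    n_species: int = 30
    recordings_min: int = 2
    recordings_max: int = 6
    lam: float = 1.0
    sigma2: float = 1.0
    n_trees: int = 100
    jitter_sd: float = 0.1
    n_sites: int = 1000
    birth_rate: float = 1.0
    sr: int = 22050
    duration_range: tuple = (0.5, 3.0)
    within_species_sd_frac: float = 0.1
    log_mass_mean: float = np.log(50.0)  # median mass 50 g
    log_mass_sigma2: float = 0.5


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete in-memory synthetic study plus its ground truth."""

    tree: dendropy.Tree = field(repr=False)
    ensemble: list = field(repr=False)
    trait_table: pd.DataFrame = field(repr=False)
    alignment: dict = field(repr=False)
    body_masses: pd.Series = field(repr=False)
    recordings: dict = field(repr=False)  # species -> list[Waveform]
    ground_truth: dict = field(repr=False)

    @property
    def species(self) -> tuple:
        return tuple(self.trait_table.index)


def generate_study(design: StudyDesign | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a fully consistent synthetic study from one master seed."""
    d = design or StudyDesign()
    if d.recordings_min < 1 or d.recordings_max < d.recordings_min:
        raise ValueError("invalid recordings/species range")
    tree = simulate_yule_tree(d.n_species, d.birth_rate, seed=derive_seed(seed, "tree"))
    ensemble = jitter_ensemble(
        tree, d.n_trees, d.jitter_sd, seed=derive_seed(seed, "ensemble")
    )
    traits = simulate_lambda_bm_traits(
        tree, sigma2=d.sigma2, lam=d.lam,
        trait_names=list(LATENT_TRAITS) + ["log_mass"],
        seed=derive_seed(seed, "traits"),
    )
    log_mass = d.log_mass_mean + np.sqrt(d.log_mass_sigma2 / max(d.sigma2, 1e-12)) * (
        traits["log_mass"] if d.sigma2 > 0 else 0.0
    )
    body_masses = np.exp(log_mass).rename("body_mass_g")
    trait_table = traits[list(LATENT_TRAITS)]
    alignment = simulate_jc_alignment(
        tree, n_sites=d.n_sites, seed=derive_seed(seed, "alignment")
    )
    within_sd = d.within_species_sd_frac * np.sqrt(d.sigma2)  # unit-depth tree
    recordings = {}
    for sp in trait_table.index:
        k_rng = np.random.default_rng(derive_seed(seed, "nrec", sp))
        n_rec = int(k_rng.integers(d.recordings_min, d.recordings_max + 1))
        recs = []
        for j in range(n_rec):
            rec_rng = np.random.default_rng(derive_seed(seed, "rec", sp, j))
            jittered = trait_table.loc[sp] + rec_rng.normal(
                0.0, within_sd, size=len(LATENT_TRAITS)
            )
            dur = float(rec_rng.uniform(*d.duration_range))
            recs.append(
                synthesize_vocalization(
                    jittered, duration_s=dur, sr=d.sr,
                    seed=derive_seed(seed, "wav", sp, j),
                )
            )
        recordings[sp] = recs
    ground_truth = {
        "seed": seed,
        "lambda": d.lam,
        "sigma2": d.sigma2,
        "n_species": d.n_species,
        "n_trees": d.n_trees,
        "jitter_sd": d.jitter_sd,
        "n_sites": d.n_sites,
    }
    return SyntheticStudy(
        tree=tree,
        ensemble=ensemble,
        trait_table=trait_table,
        alignment=alignment,
        body_masses=body_masses,
        recordings=recordings,
        ground_truth=ground_truth,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write the study bundle to disk; returns {kind: path or [paths]}.

    Layout: ``audio/<species>__<idx>.wav``, ``trees.nwk`` (one Newick per
    line, first tree also in ``tree.nwk``), ``alignment.fasta``,
    ``body_mass.csv``, ``traits.csv``, ``ground_truth.csv``.
    """
    out = Path(out_dir)
    audio_dir = out / "audio"
    try:
        audio_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {audio_dir}: {err}") from err
    manifest = {"audio": []}
    for sp, recs in study.recordings.items():
        for j, w in enumerate(recs):
            path = audio_dir / f"{sp}__{j}.wav"
            write_wav(path, w)
            manifest["audio"].append(str(path))
    tree_path = out / "tree.nwk"
    study.tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    trees_path = out / "trees.nwk"
    with open(trees_path, "w") as fh:
        for t in study.ensemble:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")
    fasta_path = out / "alignment.fasta"
    with open(fasta_path, "w") as fh:
        for sp, seq in study.alignment.items():
            fh.write(f">{sp}\n{seq}\n")
    mass_path = out / "body_mass.csv"
    study.body_masses.rename_axis("species_id").to_csv(mass_path)
    traits_path = out / "traits.csv"
    study.trait_table.rename_axis("species_id").to_csv(traits_path)
    gt_path = out / "ground_truth.csv"
    pd.DataFrame([study.ground_truth]).to_csv(gt_path, index=False)
    manifest.update(
        tree=str(tree_path), trees=str(trees_path), alignment=str(fasta_path),
        body_mass=str(mass_path), traits=str(traits_path), ground_truth=str(gt_path),
    )
    return manifest
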
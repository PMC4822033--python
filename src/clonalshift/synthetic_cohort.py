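"""Synthetic clonal-evolution cohorts with known truth.

Generates paired pre-/post-chemotherapy tumour cohorts that emulate the study
conditions of a ~30-patient oesophageal adenocarcinoma trial: sub-clonal
trees, therapy bottlenecks of varying severity, polyclonal hypermutators with
multiple same-gene driver mutations, purity variation, signature-structured
mutation spectra (an ageing-like C>T-at-CpG signature with .TT>.GT changes, a
C>A-rich signature and a T>C/C>A signature), arm-scale SCNAs on a synthetic
genome, and binomial sequencing noise at configurable depth.  Every emitted
variant carries a truth record (clone, true CCFs, channel), so each
downstream pipeline stage can be validated against planted truth without any
external data.

The generative model, per patient:

1. a rooted clone tree is drawn; each clone's ``fraction`` is the cancer-cell
   fraction (CCF) of its mutations, so a child's fraction never exceeds its
   parent's;
2. treatment applies a survival multiplier to each clone's *private* cell
   population; surviving cell fractions are renormalized and post-treatment
   CCFs recomputed as subtree sums (clones falling below the extinction
   threshold die out);
3. mutations are allocated to clones and assigned 96-channel contexts from
   the patient's signature mixture (post-treatment-only mutations use a
   mixture shifted towards C>A, emulating chemotherapy-associated spectrum
   change);
4. read counts are simulated per sample: total depth ~ Poisson(depth), alt
   count ~ Binomial(depth, expected VAF), where the expected VAF accounts for
   purity, CCF and local copy number; the normal sample uses a sequencing
   error model, plus a small number of planted germline-leak and artefact
   variants to exercise the somatic filters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clonal_dynamics import expected_vaf
from .spectra_signatures import BASES, CLASSES6

__all__ = [
    "CloneNode",
    "SimConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "CompleteResponseError",
    "planted_signatures",
    "default_arm_table",
    "simulate_clone_tree",
    "apply_bottleneck",
    "assign_mutation_spectra",
    "sequence_sample",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "read_cohort_dir",
]

SCENARIOS = ("stable", "bottleneck", "polyclonal")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CompleteResponseError(ValueError):
    """All clones received survival 0: no post-treatment tumour exists."""


# ---------------------------------------------------------------------------
# Planted signatures
# ---------------------------------------------------------------------------

def _channel(cls: str, fp: str, tp: str) -> int:
    return 16 * CLASSES6.index(cls) + 4 * BASES.index(fp) + BASES.index(tp)


def planted_signatures() -> np.ndarray:
    """Three 96-channel signatures (columns, each summing to 1).

    Column 0 ("ageing-like"): C>T at CpG plus .TT>.GT changes.
    Column 1 ("C>A-rich"):    mass concentrated on C>A channels.
    Column 2 ("T>C / C>A"):   .TT>.CT changes plus C>A.
    """
    sigs = np.full((96, 3), 1.0)  # flat floor on every channel

    s = sigs[:, 0]
    for fp in BASES:  # C>T at CpG (3' G)
        s[_channel("C>T", fp, "G")] += 40.0
    for fp in BASES:  # .TT>.GT: T>G with 3' T
        s[_channel("T>G", fp, "T")] += 18.0
    for fp in BASES:  # residual ageing C>T at non-CpG
        for tp in "ACT":
            s[_channel("C>T", fp, tp)] += 3.0

    s = sigs[:, 1]
    for fp in BASES:  # C>A everywhere
        for tp in BASES:
            s[_channel("C>A", fp, tp)] += 16.0

    s = sigs[:, 2]
    for fp in BASES:  # .TT>.CT: T>C with 3' T
        s[_channel("T>C", fp, "T")] += 28.0
    for fp in BASES:
        for tp in BASES:
            s[_channel("C>A", fp, tp)] += 5.0

    return sigs / sigs.sum(axis=0, keepdims=True)


def _ta_component() -> np.ndarray:
    """Uniform T>A component used to plant the response-associated T>A excess."""
    v = np.zeros(96)
    for fp in BASES:
        for tp in BASES:
            v[_channel("T>A", fp, tp)] = 1.0
    return v / v.sum()


# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------

@dataclass
class CloneNode:
    clone_id: int
    parent_id: int | None
    n_private_mutations: int = 0
    fraction_pre: float = 0.0
    fraction_post: float = 0.0
    survival: float = 1.0


@dataclass
class SimConfig:
    """Cohort-level study conditions.

    Defaults mirror the emulated trial: 30 patients, a 11:10:3 split of
    stable / bottleneck / polyclonal dynamics among classifiable cancers,
    median exome depth ~75x (deep-panel mode 1,800x), median burden 373,
    hypertriploid genomes, and a median of 18 large SCNAs per cancer.
    """

    n_patients: int = 30
    scenario_mix: tuple = (11 / 24, 10 / 24, 3 / 24)  # stable, bottleneck, polyclonal
    mean_burden: int = 373
    depth_pre: float = 75.0
    depth_post: float = 75.0
    depth_normal: float = 75.0
    panel_depth: float = 1800.0
    purity_pre: float = 0.65
    purity_post: float = 0.65
    purity_jitter: float = 0.10
    ploidy: float = 3.0
    n_large_scna: int = 18
    signature_weights: tuple | None = None  # fixed mixture; None = per-patient draw
    seed: int = 0
    # secondary knobs
    extinction_threshold: float = 1e-4
    error_rate: float = 1e-3
    post_only_mean: float = 30.0
    hypermutator_factor: float = 20.0
    msi_fraction_polyclonal: float = 2 / 3
    excluded_fraction: float = 0.2   # patients with degraded post-treatment samples
    germline_leak_mean: float = 20.0
    artifact_rate: float = 0.01     # popfreq / PoN / segdup / low-mappability each
    probes_per_arm: int = 120
    scna_noise_sd: float = 0.10
    scna_logr_range: tuple = (0.3, 0.5)

    def __post_init__(self):
        if abs(sum(self.scenario_mix) - 1.0) > 1e-9:
            raise ValueError("scenario_mix must sum to 1")
        if min(self.depth_pre, self.depth_post, self.depth_normal, self.panel_depth) < 1:
            raise ValueError("depths must be >= 1")
        for p in (self.purity_pre, self.purity_post):
            if not 0 < p <= 1:
                raise ValueError("purities must be in (0, 1]")


@dataclass
class SyntheticPatient:
    patient_id: str
    scenario: str
    clinical: dict
    msi: bool
    purity_pre: float
    purity_post: float
    histology_content_post: float
    tree: list
    variants: pd.DataFrame
    truth: pd.DataFrame
    scna_probes: pd.DataFrame
    arm_events_pre: list
    arm_events_post: list
    expected_excluded: bool = False


@dataclass
class SyntheticCohort:
    config: SimConfig
    patients: list
    arm_table: pd.DataFrame = field(default_factory=lambda: default_arm_table())


# ---------------------------------------------------------------------------
# Clone trees and bottlenecks
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_clone_tree(n_clones: int, seed=0) -> list[CloneNode]:
    """Random rooted clone tree with tree-consistent pre-treatment CCFs.

    The root has fraction_pre = 1 (all cancer cells).  Each further clone
    attaches to a uniformly chosen existing clone and claims a uniform share
    of its parent's currently unallocated cell fraction, which guarantees
    child <= parent and sibling sums <= parent.  Deterministic given seed.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = _as_rng(seed)
    nodes = [CloneNode(clone_id=0, parent_id=None, fraction_pre=1.0, fraction_post=1.0)]
    unallocated = {0: 1.0}
    for cid in range(1, n_clones):
        parent = int(rng.integers(0, cid))
        share = float(rng.uniform(0.15, 0.75)) * unallocated[parent]
        nodes.append(CloneNode(clone_id=cid, parent_id=parent,
                               fraction_pre=share, fraction_post=share))
        unallocated[parent] -= share
        unallocated[cid] = share
    return nodes


def _children(tree: list[CloneNode]) -> dict:
    ch: dict = {n.clone_id: [] for n in tree}
    for n in tree:
        if n.parent_id is not None:
            ch[n.parent_id].append(n.clone_id)
    return ch


def cell_fractions(tree: list[CloneNode], which: str = "pre") -> dict:
    """Private cell fraction per clone: own CCF minus the children's CCFs."""
    attr = f"fraction_{which}"
    ch = _children(tree)
    by_id = {n.clone_id: n for n in tree}
    out = {}
    for n in tree:
        cf = getattr(n, attr) - sum(getattr(by_id[c], attr) for c in ch[n.clone_id])
        out[n.clone_id] = max(0.0, cf)
    return out


def apply_bottleneck(tree: list[CloneNode], survival_by_clone: dict,
                     extinction_threshold: float = 1e-4) -> list[CloneNode]:
    """Apply per-clone survival multipliers at treatment.

    Each clone's private cell population is scaled by its survival
    multiplier; the surviving populations are renormalized to sum to 1 and
    post-treatment CCFs are recomputed as subtree sums, which preserves tree
    consistency.  Clones whose post-treatment CCF falls below the extinction
    threshold are set to 0.  Raises :class:`CompleteResponseError` when no
    cells survive.
    """
    surv = {n.clone_id: float(survival_by_clone.get(n.clone_id, 1.0)) for n in tree}
    if any(s < 0 for s in surv.values()):
        raise ValueError("survival multipliers must be >= 0")
    cf = cell_fractions(tree, "pre")
    post_cells = {cid: cf[cid] * surv[cid] for cid in cf}
    total = sum(post_cells.values())
    if total <= 0:
        raise CompleteResponseError("all clones eliminated: complete response")
    post_cells = {cid: v / total for cid, v in post_cells.items()}

    ch = _children(tree)

    def subtree_sum(cid: int) -> float:
        return post_cells[cid] + sum(subtree_sum(c) for c in ch[cid])

    for n in tree:
        f = subtree_sum(n.clone_id)
        n.fraction_post = 0.0 if f < extinction_threshold else f
        n.survival = surv[n.clone_id]
    return tree


# ---------------------------------------------------------------------------
# Spectra and sequencing
# ---------------------------------------------------------------------------

def assign_mutation_spectra(n_mutations: int, signature_weights, seed=0,
                            signatures: np.ndarray | None = None) -> np.ndarray:
    """Draw one 96-channel context per mutation from a signature mixture."""
    w = np.asarray(signature_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("signature weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("signature weights must not all be zero")
    sigs = planted_signatures() if signatures is None else np.asarray(signatures, dtype=float)
    if sigs.shape[0] != 96 or sigs.shape[1] != w.size:
        raise ValueError("signatures must be 96 x len(weights)")
    mix = sigs @ (w / w.sum())
    mix = mix / mix.sum()
    rng = _as_rng(seed)
    return rng.choice(96, size=n_mutations, p=mix)


def sequence_sample(ccf, total_cn, purity: float, depth: float, seed=0,
                    mutated_cn=1.0, error_rate: float = 0.0):
    """Simulate (depth, alt) read counts for one sample.

    Total depth ~ Poisson(depth); alt ~ Binomial(total, expected VAF) with
    expected VAF = purity*ccf*mutated_cn / (purity*total_cn + 2(1-purity)),
    plus a per-read error floor (used for the normal sample).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _as_rng(seed)
    ccf = np.asarray(ccf, dtype=float)
    ev = expected_vaf(ccf, purity, np.asarray(total_cn, dtype=float), mutated_cn)
    ev = np.clip(ev + error_rate, 0.0, 1.0)
    d = rng.poisson(depth, size=ccf.shape)
    alt = rng.binomial(d, ev)
    return d, alt


# ---------------------------------------------------------------------------
# Synthetic genome
# ---------------------------------------------------------------------------

def default_arm_table() -> pd.DataFrame:
    """Synthetic 22-autosome arm table (cytoband-style TSV schema).

    Arm lengths vary across chromosomes; this is a stand-in coordinate system
    for simulation, not the human genome.
    """
    rows = []
    for i in range(1, 23):
        p_len = 50_000_000 + 2_000_000 * i
        q_len = 70_000_000 + 3_000_000 * i
        rows.append({"chrom": str(i), "arm": f"{i}p", "start": 1, "end": p_len})
        rows.append({"chrom": str(i), "arm": f"{i}q", "start": p_len + 1, "end": p_len + q_len})
    return pd.DataFrame(rows)


_REF_FOR_CLASS = {c: c.split(">")[0] for c in CLASSES6}
_ALT_FOR_CLASS = {c: c.split(">")[1] for c in CLASSES6}


def _alleles_from_channels(channels: np.ndarray, rng: np.random.Generator):
    """Ref/alt alleles for each channel, with a random strand flip."""
    refs, alts = [], []
    flip = rng.random(channels.size) < 0.5
    for ch, fl in zip(channels, flip):
        cls = CLASSES6[ch // 16]
        ref, alt = _REF_FOR_CLASS[cls], _ALT_FOR_CLASS[cls]
        if fl:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        refs.append(ref)
        alts.append(alt)
    return np.array(refs), np.array(alts)


# ---------------------------------------------------------------------------
# Patient-level generation
# ---------------------------------------------------------------------------

_MANDARD_P = {
    "bottleneck": [0.30, 0.50, 0.10, 0.10],
    "stable": [0.05, 0.15, 0.40, 0.40],
    "polyclonal": [0.0, 1 / 3, 1 / 3, 1 / 3],
}  # over Mandard grades 2..5


def _build_scenario_tree(scenario: str, rng: np.random.Generator):
    """Scenario-specific clone tree plus survival map and MSI flag."""
    if scenario == "stable":
        tree = simulate_clone_tree(int(rng.integers(2, 7)), rng)
        survival = {n.clone_id: 1.0 for n in tree}
        return tree, survival, False
    if scenario == "bottleneck":
        major = float(rng.uniform(0.55, 0.8))
        minor = float(rng.uniform(0.08, 0.18))
        tree = [
            CloneNode(0, None, fraction_pre=1.0),
            CloneNode(1, 0, fraction_pre=major),
            CloneNode(2, 0, fraction_pre=minor),
        ]
        if rng.random() < 0.5:  # extra sub-clone inside the doomed major clone
            tree.append(CloneNode(3, 1, fraction_pre=major * float(rng.uniform(0.15, 0.35))))
        survival = {n.clone_id: float(rng.uniform(0.0005, 0.004)) for n in tree}
        survival[2] = float(rng.uniform(0.5, 1.0))
        return tree, survival, False
    if scenario == "polyclonal":
        a = float(rng.uniform(0.44, 0.5))
        b = float(rng.uniform(0.44, min(0.52, 0.99 - a)))
        tree = [
            CloneNode(0, None, fraction_pre=1.0),  # founder container, no private muts
            CloneNode(1, 0, fraction_pre=a),       # lineage A (lost after therapy)
            CloneNode(2, 0, fraction_pre=b),       # lineage B (persists)
            CloneNode(3, 2, fraction_pre=b * float(rng.uniform(0.4, 0.7))),  # B sub-clone, expands
        ]
        survival = {0: 0.0, 1: float(rng.uniform(0.0, 0.01)),
                    2: float(rng.uniform(0.4, 0.8)), 3: float(rng.uniform(0.9, 1.5))}
        return tree, survival, bool(rng.random() < 2 / 3)
    raise ValueError(f"unknown scenario {scenario!r}")


def _signature_weights(age: float, responder: bool, rng: np.random.Generator,
                       fixed=None) -> np.ndarray:
    """Per-patient mixture over (ageing, C>A, T>C/C>A, T>A-excess) components."""
    if fixed is not None:
        w = np.asarray(fixed, dtype=float)
        return w / w.sum()
    w_age = max(0.15, 0.55 + 0.004 * (age - 65.0) + rng.normal(0, 0.04))
    w_ca = rng.uniform(0.10, 0.25)
    if rng.random() < 0.07:  # occasional C>A-dominant cancer
        w_ca = rng.uniform(0.6, 0.9)
    w_s2 = rng.uniform(0.03, 0.10)
    # planted T>A excess: on top of the ~4.5% baseline T>A content of the three
    # signatures this puts responder medians near 7% and non-responders near 5%
    w_ta = rng.uniform(0.012, 0.032) if responder else rng.uniform(0.0, 0.007)
    w = np.array([w_age, w_ca, w_s2, w_ta])
    return w / w.sum()


_SHIFT_STRENGTH = {"bottleneck": 0.5, "polyclonal": 0.3, "stable": 0.15}


def _shifted_weights(w: np.ndarray, scenario: str) -> np.ndarray:
    """Post-treatment mixture: move ageing mass to the C>A component."""
    s = _SHIFT_STRENGTH[scenario]
    w2 = w.copy()
    moved = s * w2[0]
    w2[0] -= moved
    w2[1] += moved
    return w2 / w2.sum()


def simulate_patient(patient_index: int, scenario: str, config: SimConfig,
                     arm_table: pd.DataFrame | None = None) -> SyntheticPatient:
    """Generate one patient with full truth records (deterministic given config.seed)."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, patient_index])
    arm_table = default_arm_table() if arm_table is None else arm_table
    pid = f"P{patient_index + 1:03d}"

    # clinical record
    age = float(np.clip(np.round(rng.normal(65, 8)), 29, 88))
    sex = "Male" if rng.random() < 0.8 else "Female"
    mandard = int(rng.choice([2, 3, 4, 5], p=_MANDARD_P[scenario]))
    responder = mandard <= 3
    clinical = {
        "Case": pid, "Age": int(age), "Sex": sex,
        "T": int(rng.integers(1, 5)), "N": int(rng.integers(0, 3)),
        "PathR": "Yes" if responder else "No", "Mandard": mandard,
    }

    tree, survival, msi = _build_scenario_tree(scenario, rng)
    tree = apply_bottleneck(tree, survival, cfg.extinction_threshold)
    hypermutator = msi or (scenario == "polyclonal" and rng.random() < 0.5)

    # burden and clone allocation
    burden_mean = cfg.mean_burden * (cfg.hypermutator_factor if hypermutator else 1.0)
    burden = max(30, int(rng.poisson(burden_mean)))
    weights = np.array([
        n.fraction_pre if not (scenario == "polyclonal" and n.clone_id == 0) else 0.0
        for n in tree
    ])
    weights = weights / weights.sum()
    counts = rng.multinomial(burden, weights)
    for n, c in zip(tree, counts):
        n.n_private_mutations = int(c)

    # signature mixture and channels
    w_pre = _signature_weights(age, responder, rng, cfg.signature_weights)
    sigs = np.column_stack([planted_signatures(), _ta_component()])
    if cfg.signature_weights is not None and len(w_pre) == 3:
        sigs = planted_signatures()
    channels = assign_mutation_spectra(burden, w_pre, rng, sigs)

    clone_of = np.repeat([n.clone_id for n in tree], counts)
    ccf_pre = np.repeat([n.fraction_pre for n in tree], counts)
    ccf_post = np.repeat([n.fraction_post for n in tree], counts)

    # post-treatment-only mutations in surviving clones
    post_mean = cfg.post_only_mean * (cfg.hypermutator_factor if hypermutator else 1.0)
    n_post = int(rng.poisson(post_mean))
    alive = [n for n in tree if n.fraction_post > 0]
    host_w = np.array([n.fraction_post for n in alive])
    hosts = rng.choice(len(alive), size=n_post, p=host_w / host_w.sum())
    post_ccf = np.array([alive[h].fraction_post for h in hosts]) * rng.uniform(0.2, 1.0, n_post)
    w_post = _shifted_weights(w_pre, scenario) if cfg.signature_weights is None else w_pre
    post_channels = assign_mutation_spectra(n_post, w_post, rng, sigs)

    clone_of = np.concatenate([clone_of, np.array([alive[h].clone_id for h in hosts], dtype=int)])
    ccf_pre = np.concatenate([ccf_pre, np.zeros(n_post)])
    ccf_post = np.concatenate([ccf_post, post_ccf])
    channels = np.concatenate([channels, post_channels])
    n_var = clone_of.size

    # driver annotations
    genes = np.full(n_var, ".", dtype=object)
    pre_mask = ccf_pre > 0
    if scenario == "polyclonal":
        # three same-gene drivers across the two founder lineages
        for cid in (1, 2, 3):
            idx = np.where(pre_mask & (clone_of == cid))[0]
            if idx.size:
                genes[idx[0]] = "TP53"
    else:
        if rng.random() < 0.77:
            idx = np.where(pre_mask & (clone_of == 0))[0]
            if idx.size:
                genes[idx[0]] = "TP53"
        for g in ("NOTCH1", "ARID1A", "SMARCA4", "CDKN2A"):
            if rng.random() < 0.25:
                idx = np.where(pre_mask & (genes == "."))[0]
                if idx.size:
                    genes[rng.choice(idx)] = g

    # genomic coordinates and alleles
    chrom_rows = arm_table.groupby("chrom")["end"].max()
    chroms = rng.choice(chrom_rows.index.to_numpy(), size=n_var)
    pos = np.array([rng.integers(1, chrom_rows[c]) for c in chroms], dtype=np.int64)
    refs, alts = _alleles_from_channels(channels, rng)

    total_cn = np.full(n_var, 2.0 if msi else float(np.round(cfg.ploidy)))

    # purity (jittered around the configured means) and degraded samples
    expected_excluded = bool(rng.random() < cfg.excluded_fraction)
    jit = cfg.purity_jitter
    purity_pre = float(np.clip(cfg.purity_pre + rng.uniform(-jit, jit), 0.2, 0.95))
    purity_post = float(np.clip(cfg.purity_post + rng.uniform(-jit, jit), 0.2, 0.95))
    histology_post = float(rng.uniform(0.35, 0.75))
    depth_post = cfg.depth_post
    if expected_excluded:
        purity_post = float(rng.uniform(0.05, 0.25))
        histology_post = float(rng.uniform(0.02, 0.15))

    # sequencing
    nd, na = sequence_sample(np.zeros(n_var), total_cn, max(purity_pre, 1e-3),
                             cfg.depth_normal, rng, error_rate=cfg.error_rate)
    pdep, palt = sequence_sample(ccf_pre, total_cn, purity_pre, cfg.depth_pre, rng,
                                 error_rate=cfg.error_rate)
    qdep, qalt = sequence_sample(ccf_post, total_cn, purity_post, depth_post, rng,
                                 error_rate=cfg.error_rate)

    variants = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": refs, "alt": alts, "gene": genes,
        "context96": channels.astype(int),
        "normal_depth": nd, "normal_alt": na,
        "pre_depth": pdep, "pre_alt": palt,
        "post_depth": qdep, "post_alt": qalt,
        "population_frequency": 0.0,
        "panel_of_normals_hit": False,
        "segdup_region": False,
        "mappability": 1.0,
        "total_cn": total_cn,
    })

    # planted filter-fodder: artefact annotations and germline leak-through
    n = len(variants)
    nondriver = (variants["gene"] == ".").to_numpy()
    for col, val in (("population_frequency", lambda k: rng.uniform(0.01, 0.2, k)),
                     ("mappability", lambda k: rng.uniform(0.3, 0.79, k))):
        mask = (rng.random(n) < cfg.artifact_rate) & nondriver
        variants.loc[mask, col] = val(int(mask.sum()))
    for col in ("panel_of_normals_hit", "segdup_region"):
        mask = (rng.random(n) < cfg.artifact_rate) & nondriver
        variants.loc[mask, col] = True
    n_germ = int(rng.poisson(cfg.germline_leak_mean))
    if n_germ:
        gd = rng.poisson(cfg.depth_normal, n_germ)
        g_pre_d = rng.poisson(cfg.depth_pre, n_germ)
        g_post_d = rng.poisson(depth_post, n_germ)
        germ = pd.DataFrame({
            "chrom": rng.choice(chrom_rows.index.to_numpy(), size=n_germ),
            "pos": rng.integers(1, 50_000_000, n_germ),
            "ref": "C", "alt": "T", "gene": ".",
            "context96": rng.integers(0, 96, n_germ),
            "normal_depth": gd, "normal_alt": rng.binomial(gd, 0.5),
            "pre_depth": g_pre_d, "pre_alt": rng.binomial(g_pre_d, 0.5),
            "post_depth": g_post_d, "post_alt": rng.binomial(g_post_d, 0.5),
            "population_frequency": 0.0, "panel_of_normals_hit": False,
            "segdup_region": False, "mappability": 1.0,
            "total_cn": 2.0,
        })
        variants = pd.concat([variants, germ], ignore_index=True)

    truth = pd.DataFrame({
        "chrom": variants["chrom"], "pos": variants["pos"],
        "ref": variants["ref"], "alt": variants["alt"],
        "clone_id": np.concatenate([clone_of, np.full(n_germ, -1, dtype=int)]),
        "ccf_pre": np.concatenate([ccf_pre, np.zeros(n_germ)]),
        "ccf_post": np.concatenate([ccf_post, np.zeros(n_germ)]),
        "context96": variants["context96"],
        "total_cn": variants["total_cn"],
        "germline": np.concatenate([np.zeros(n_var, bool), np.ones(n_germ, bool)]),
    })

    probes, ev_pre, ev_post = _simulate_scna(rng, cfg, arm_table, msi)

    return SyntheticPatient(
        patient_id=pid, scenario=scenario, clinical=clinical, msi=msi,
        purity_pre=purity_pre, purity_post=purity_post,
        histology_content_post=histology_post,
        tree=tree, variants=variants, truth=truth,
        scna_probes=probes, arm_events_pre=ev_pre, arm_events_post=ev_post,
        expected_excluded=expected_excluded,
    )


def _simulate_scna(rng, cfg: SimConfig, arm_table: pd.DataFrame, msi: bool):
    """Plant arm-scale SCNAs and emit noisy per-probe logR for both samples."""
    arms = arm_table["arm"].tolist()
    n_events = 2 if msi else min(cfg.n_large_scna, len(arms))
    chosen = rng.choice(len(arms), size=n_events, replace=False)
    lo, hi = cfg.scna_logr_range
    pre_events = {
        arms[i]: (("gain" if rng.random() < 0.5 else "loss"), float(rng.uniform(lo, hi)))
        for i in chosen
    }
    keep_p = float(rng.uniform(0.3, 0.75))
    post_events = {a: e for a, e in pre_events.items() if rng.random() < keep_p}
    n_new = int(rng.poisson(1 if msi else 6))
    free = [a for a in arms if a not in post_events]
    for i in rng.choice(len(free), size=min(n_new, len(free)), replace=False):
        post_events[free[i]] = (("gain" if rng.random() < 0.5 else "loss"),
                                float(rng.uniform(lo, hi)))

    rows = []
    for _, arm in arm_table.iterrows():
        pos = np.linspace(arm["start"], arm["end"], cfg.probes_per_arm).astype(np.int64)
        for sample, events in (("pre", pre_events), ("post", post_events)):
            base = 0.0
            if arm["arm"] in events:
                direction, mag = events[arm["arm"]]
                base = mag if direction == "gain" else -mag
            logr = base + rng.normal(0, cfg.scna_noise_sd, cfg.probes_per_arm)
            rows.append(pd.DataFrame({
                "sample": sample, "chrom": arm["chrom"], "pos": pos, "logr": logr,
            }))
    probes = pd.concat(rows, ignore_index=True)
    to_list = lambda ev: sorted((a, d) for a, (d, _) in ev.items())
    return probes, to_list(pre_events), to_list(post_events)


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort; scenario per patient drawn from the scenario mix."""
    cfg = config or SimConfig()
    rng = np.random.default_rng([cfg.seed, 10**6])
    arm_table = default_arm_table()
    scenarios = rng.choice(SCENARIOS, size=cfg.n_patients, p=list(cfg.scenario_mix))
    patients = [
        simulate_patient(i, scenarios[i], cfg, arm_table) for i in range(cfg.n_patients)
    ]
    return SyntheticCohort(config=cfg, patients=patients, arm_table=arm_table)


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CTX96,Number=1,Type=Integer,Description="Trinucleotide channel 0-95">
##INFO=<ID=POPFREQ,Number=1,Type=Float,Description="Max germline population frequency">
##INFO=<ID=PON,Number=0,Type=Flag,Description="Panel-of-normals hit">
##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="Segmental duplication region">
##INFO=<ID=MAPPABILITY,Number=1,Type=Float,Description="Mappability score">
##INFO=<ID=TCN,Number=1,Type=Float,Description="Local total copy number">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tPRE\tPOST
"""


def _write_vcf(variants: pd.DataFrame, path: Path):
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for row in variants.itertuples(index=False):
            info = [f"GENE={row.gene}", f"CTX96={int(row.context96)}",
                    f"POPFREQ={row.population_frequency:.6g}",
                    f"MAPPABILITY={row.mappability:.6g}", f"TCN={row.total_cn:.6g}"]
            if row.panel_of_normals_hit:
                info.append("PON")
            if row.segdup_region:
                info.append("SEGDUP")
            cells = []
            for s in ("normal", "pre", "post"):
                d = int(getattr(row, f"{s}_depth"))
                a = int(getattr(row, f"{s}_alt"))
                cells.append(f"{d}:{d - a},{a}")
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + ";".join(info) + "\tDP:AD\t" + "\t".join(cells) + "\n"
            )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write the cohort in the pipeline's input formats.

    Per patient: ``<id>.vcf`` (NORMAL/PRE/POST genotype columns, DP and AD
    FORMAT fields), ``<id>.variants.tsv`` mirror, ``<id>.truth.tsv`` and
    ``<id>.scna_probes.tsv``.  Cohort level: ``clinical.tsv`` (Table-1-style
    columns), ``arms.tsv``, ``cohort_truth.tsv`` and a run manifest.
    Deterministic: identical config + seed give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clin_rows, truth_rows = [], []
    for p in cohort.patients:
        variants = p.variants.sort_values(["chrom", "pos", "alt"], kind="mergesort")
        _write_vcf(variants, out / f"{p.patient_id}.vcf")
        variants.to_csv(out / f"{p.patient_id}.variants.tsv", sep="\t", index=False,
                        float_format="%.6g")
        p.truth.to_csv(out / f"{p.patient_id}.truth.tsv", sep="\t", index=False,
                       float_format="%.6g")
        p.scna_probes.to_csv(out / f"{p.patient_id}.scna_probes.tsv", sep="\t",
                             index=False, float_format="%.6g")
        clin_rows.append(p.clinical)
        truth_rows.append({
            "Case": p.patient_id, "scenario": p.scenario, "msi": p.msi,
            "purity_pre": p.purity_pre, "purity_post": p.purity_post,
            "histology_content_post": p.histology_content_post,
            "expected_excluded": p.expected_excluded,
        })
    cols = ["Case", "Age", "Sex", "T", "N", "PathR", "Mandard"]
    pd.DataFrame(clin_rows, columns=cols).to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.arm_table.to_csv(out / "arms.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "cohort_truth.tsv", sep="\t", index=False,
                                    float_format="%.6g")
    with open(out / "manifest.txt", "w") as fh:
        for k, v in dataclasses.asdict(cohort.config).items():
            fh.write(f"{k}: {v}\n")
    return out


def read_cohort_dir(cohort_dir) -> SyntheticCohort:
    """Reconstruct a cohort object from a directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t", dtype={"Case": str})
    meta = pd.read_csv(d / "cohort_truth.tsv", sep="\t", dtype={"Case": str})
    arm_table = pd.read_csv(d / "arms.tsv", sep="\t", dtype={"chrom": str, "arm": str})
    patients = []
    for crow, mrow in zip(clinical.to_dict("records"), meta.to_dict("records")):
        pid = crow["Case"]
        variants = pd.read_csv(d / f"{pid}.variants.tsv", sep="\t", dtype={"chrom": str})
        truth = pd.read_csv(d / f"{pid}.truth.tsv", sep="\t", dtype={"chrom": str})
        probes = pd.read_csv(d / f"{pid}.scna_probes.tsv", sep="\t",
                             dtype={"chrom": str, "sample": str})
        patients.append(SyntheticPatient(
            patient_id=pid, scenario=mrow["scenario"], clinical=crow,
            msi=bool(mrow["msi"]), purity_pre=float(mrow["purity_pre"]),
            purity_post=float(mrow["purity_post"]),
            histology_content_post=float(mrow["histology_content_post"]),
            tree=[], variants=variants, truth=truth, scna_probes=probes,
            arm_events_pre=[], arm_events_post=[],
            expected_excluded=bool(mrow["expected_excluded"]),
        ))
    return SyntheticCohort(config=SimConfig(n_patients=len(patients)),
                           patients=patients, arm_table=arm_table)
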
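"""Clonal-dynamics analysis of paired pre-/post-treatment tumour samples.

Converts variant allele frequencies to cancer cell fractions (CCFs) using
tumour purity and local copy number, clusters mutations into clones with a
finite binomial-mixture EM over the joint (pre, post) read counts (model size
chosen by BIC), classifies per-mutation trajectories, quantifies whether
apparent mutation losses are explainable by read sampling alone, and applies
the per-patient evolution decision rule:

    excluded (failed purity QC)
    -> polyclonal (discordant same-gene driver set, or hypermutator with
       loss AND gain across the VAF spectrum)
    -> bottleneck (substantial loss of high-VAF mutations not explainable by
       sampling, a non-trivial shared set, and an expanding minor clone)
    -> stable otherwise.

All quantitative cutoffs are explicit in :class:`EvolutionThresholds` and are
reported with every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_driver_genes",
    "ClusterParams",
    "EvolutionThresholds",
    "CloneCluster",
    "EvolutionCall",
    "expected_vaf",
    "ccf_from_vaf",
    "select_for_clustering",
    "cluster_clones",
    "classify_trajectory",
    "sampling_loss_probability",
    "detect_polyclonality",
    "classify_evolution",
    "compute_patient_metrics",
    "vaf_cv",
    "spatial_concordance",
]


def load_driver_genes(path=None) -> frozenset:
    """Driver-gene symbols from a one-per-line text file (default: shipped list)."""
    if path is None:
        from importlib.resources import files

        path = files("clonalshift.data").joinpath("eac_drivers.txt")
        text = path.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    genes = [ln.strip() for ln in text.splitlines()]
    return frozenset(g for g in genes if g and not g.startswith("#"))


# ---------------------------------------------------------------------------
# CCF model
# ---------------------------------------------------------------------------

def expected_vaf(ccf, purity, total_cn=2.0, mutated_cn=1.0):
    """Expected VAF of a mutation at cancer-cell fraction ``ccf``.

    VAF = purity * ccf * mutated_cn / (purity * total_cn + 2 (1 - purity)).
    """
    ccf = np.asarray(ccf, dtype=float)
    if np.any(np.asarray(purity) <= 0) or np.any(np.asarray(purity) > 1):
        raise ValueError("purity must be in (0, 1]")
    denom = purity * np.asarray(total_cn, dtype=float) + 2.0 * (1.0 - purity)
    return purity * ccf * np.asarray(mutated_cn, dtype=float) / denom


def ccf_from_vaf(vaf, purity, total_cn=2.0, mutated_cn=1.0, clip_at: float = 1.5):
    """Invert :func:`expected_vaf`: CCF = vaf (purity*cn + 2(1-purity)) / (purity*mult).

    Values above ``clip_at`` (copy-number error) are clipped; a companion
    boolean array flags clipped entries when the input is an array.
    """
    vaf = np.asarray(vaf, dtype=float)
    if np.any(np.asarray(purity) <= 0) or np.any(np.asarray(purity) > 1):
        raise ValueError("purity must be in (0, 1]")
    if np.any(np.asarray(total_cn) < 1) or np.any(np.asarray(mutated_cn) < 1):
        raise ValueError("copy numbers must be >= 1")
    ccf = vaf * (purity * np.asarray(total_cn, dtype=float) + 2.0 * (1.0 - purity)) / (
        purity * np.asarray(mutated_cn, dtype=float)
    )
    clipped = ccf > clip_at
    ccf = np.minimum(ccf, clip_at)
    if ccf.ndim == 0:
        return float(ccf)
    return ccf, clipped


# ---------------------------------------------------------------------------
# Selection of mutations for clustering
# ---------------------------------------------------------------------------

def select_for_clustering(
    variants: pd.DataFrame,
    drivers=(),
    min_coverage: int = 60,
    rescue_vaf: float = 0.03,
    subsample_cap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag mutations for clone clustering.

    Inclusion reasons (mirroring the deep-coverage inclusion rules used for
    multi-sample clonal inference):

    - ``coverage60``: detected in both samples with >= ``min_coverage`` reads
      in at least one of them;
    - ``low_vaf_rescue``: detected in exactly one sample, the other below the
      ``rescue_vaf`` allelic ratio (captures lost / newly arisen clones);
    - ``driver``: annotated driver-gene mutations, kept regardless of coverage.

    Patients with more included mutations than ``subsample_cap`` are
    down-sampled uniformly at random (seeded); drivers are always kept.
    """
    df = variants.copy()
    pre_present = df["pre_vaf"] >= rescue_vaf
    post_present = df["post_vaf"] >= rescue_vaf
    cov_ok = np.maximum(df["pre_depth"], df["post_depth"]) >= min_coverage
    is_driver = df["gene"].isin(set(drivers)) if len(drivers) else pd.Series(False, index=df.index)

    reason = np.full(len(df), "", dtype=object)
    reason[(pre_present & post_present & cov_ok).to_numpy()] = "coverage60"
    reason[(pre_present ^ post_present).to_numpy()] = "low_vaf_rescue"
    reason[is_driver.to_numpy()] = "driver"
    df["inclusion_reason"] = reason
    df["included_in_clustering"] = reason != ""

    included_idx = df.index[df["included_in_clustering"]]
    if len(included_idx) > subsample_cap:
        rng = np.random.default_rng(seed)
        driver_idx = df.index[df["included_in_clustering"] & is_driver]
        other_idx = df.index[df["included_in_clustering"] & ~is_driver]
        n_keep = max(0, subsample_cap - len(driver_idx))
        keep = rng.choice(other_idx, size=min(n_keep, len(other_idx)), replace=False)
        keep_set = set(driver_idx) | set(keep)
        df.loc[~df.index.isin(keep_set), "included_in_clustering"] = False
    return df


# ---------------------------------------------------------------------------
# Binomial-mixture EM clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterParams:
    max_clusters: int = 8
    restarts: int = 20
    max_iterations: int = 500
    tolerance: float = 1e-6
    subsample_cap: int = 500
    seed: int = 0

    def __post_init__(self):
        if min(self.max_clusters, self.restarts, self.max_iterations) < 1 or self.tolerance <= 0:
            raise ValueError("cluster parameters must be positive")


@dataclass
class CloneCluster:
    cluster_id: int
    member_index: np.ndarray
    center_pre: float
    center_post: float
    size: int
    vaf_pre: float = 0.0
    vaf_post: float = 0.0


def _em_binomial_mixture(alt, dep, K: int, restarts: int, max_iter: int, tol: float,
                         rng: np.random.Generator):
    """Batched EM for a K-component joint binomial mixture over R restarts.

    ``alt``/``dep`` are (n, 2) arrays (pre, post).  All restarts run as one
    batch; converged restarts (relative log-likelihood change below ``tol``)
    are dropped from the batch as they finish.  Returns the best restart's
    (loglik, theta (K,2), pi (K,)).
    """
    n = alt.shape[0]
    eps = 1e-6
    obs_vaf = alt / np.maximum(dep, 1)
    # init: component vafs from randomly chosen observations, jittered
    idx = rng.integers(0, n, size=(restarts, K))
    theta = np.clip(obs_vaf[idx] + rng.uniform(-0.02, 0.02, size=(restarts, K, 2)),
                    eps, 1 - eps)
    pi = np.full((restarts, K), 1.0 / K)

    alt_b = alt[None, :, None, :]  # (1, n, 1, 2)
    dep_b = dep[None, :, None, :]
    ll_prev = np.full(restarts, -np.inf)
    best_ll, best_theta, best_pi = -np.inf, theta[0], pi[0]
    for _ in range(max_iter):
        th = theta[:, None, :, :]  # (R, 1, K, 2)
        logp = (alt_b * np.log(th) + (dep_b - alt_b) * np.log1p(-th)).sum(axis=3)
        logp += np.log(np.maximum(pi, 1e-300))[:, None, :]
        m = logp.max(axis=2, keepdims=True)
        lse = m[..., 0] + np.log(np.exp(logp - m).sum(axis=2))
        ll = lse.sum(axis=1)  # (R,)
        gamma = np.exp(logp - lse[..., None])  # (R, n, K)
        # M-step
        pi = gamma.sum(axis=1) / n
        num = np.einsum("rnk,ns->rks", gamma, alt)
        den = np.einsum("rnk,ns->rks", gamma, dep)
        theta = np.clip(num / np.maximum(den, 1e-12), eps, 1 - eps)
        done = np.abs(ll - ll_prev) < tol * (1.0 + np.abs(ll))
        ll_prev = ll
        if done.any():
            j = int(np.argmax(np.where(done, ll, -np.inf)))
            if ll[j] > best_ll:
                best_ll, best_theta, best_pi = float(ll[j]), theta[j].copy(), pi[j].copy()
            keep = ~done
            if not keep.any():
                break
            theta, pi, ll_prev = theta[keep], pi[keep], ll_prev[keep]
    if ll_prev.size:  # restarts that hit max_iter
        j = int(np.argmax(ll_prev))
        if ll_prev[j] > best_ll:
            best_ll, best_theta, best_pi = float(ll_prev[j]), theta[j], pi[j]
    # final E-step for the winner
    logp = (alt[:, None, :] * np.log(best_theta[None, :, :])
            + (dep - alt)[:, None, :] * np.log1p(-best_theta[None, :, :])).sum(axis=2)
    logp += np.log(np.maximum(best_pi, 1e-300))[None, :]
    m = logp.max(axis=1, keepdims=True)
    gamma = np.exp(logp - m)
    gamma /= gamma.sum(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))).sum())
    return ll, best_theta, best_pi, gamma


def cluster_clones(records: pd.DataFrame, params: ClusterParams | None = None,
                   purity_pre: float = 1.0, purity_post: float = 1.0,
                   total_cn: float = 2.0) -> list[CloneCluster]:
    """Cluster included mutations into clones across the sample pair.

    A finite mixture of joint binomial distributions is fitted by EM to the
    (pre, post) alt/depth counts; the number of components (1..max_clusters)
    is chosen by BIC.  Component VAF centres are converted to CCFs with the
    supplied purities and copy number.  Deterministic given ``params.seed``.
    """
    if params is None:
        params = ClusterParams()
    rec = records[records["included_in_clustering"]] if "included_in_clustering" in records else records
    n = len(rec)
    if n < 5:
        raise ValueError("need at least 5 included records to cluster")
    alt = rec[["pre_alt", "post_alt"]].to_numpy(dtype=float)
    dep = np.maximum(rec[["pre_depth", "post_depth"]].to_numpy(dtype=float), 1.0)

    best = None
    max_k = min(params.max_clusters, n)
    worse_streak = 0
    for K in range(1, max_k + 1):
        rng = np.random.default_rng((params.seed, K))
        ll, theta, pi, gamma = _em_binomial_mixture(
            alt, dep, K, params.restarts, params.max_iterations, params.tolerance, rng
        )
        n_params = 3 * K - 1  # 2 vafs per component + K-1 mixture weights
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, K, theta, gamma)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 2:  # BIC past its minimum: stop enlarging the model
                break
    _, K, theta, gamma = best
    assign = np.argmax(gamma, axis=1)
    clusters = []
    cid = 0
    for k in range(K):
        members = np.where(assign == k)[0]
        if members.size == 0:
            continue
        vp, vq = float(theta[k, 0]), float(theta[k, 1])
        c_pre = min(1.5, vp * (purity_pre * total_cn + 2 * (1 - purity_pre)) / purity_pre)
        c_post = min(1.5, vq * (purity_post * total_cn + 2 * (1 - purity_post)) / purity_post)
        clusters.append(
            CloneCluster(
                cluster_id=cid,
                member_index=rec.index.to_numpy()[members],
                center_pre=float(c_pre),
                center_post=float(c_post),
                size=int(members.size),
                vaf_pre=vp,
                vaf_post=vq,
            )
        )
        cid += 1
    return clusters


# ---------------------------------------------------------------------------
# Trajectories and sampling-loss analysis
# ---------------------------------------------------------------------------

def classify_trajectory(pre_vaf: float, post_vaf: float, detection_floor: float = 0.02) -> str:
    """'pre_only', 'post_only' or 'shared' from the two observed VAFs."""
    pre_in = pre_vaf >= detection_floor
    post_in = post_vaf >= detection_floor
    if pre_in and not post_in:
        return "pre_only"
    if post_in and not pre_in:
        return "post_only"
    return "shared"


def sampling_loss_probability(pre_vaf, post_depth, min_alt: int) -> float:
    """P(alt reads < min_alt | Binomial(post_depth, pre_vaf)).

    The probability that a mutation truly unchanged since the pre-treatment
    sample would nevertheless be missed in the post-treatment sample purely
    by read sampling.  A loss with this probability below alpha is "not
    explainable by sampling".
    """
    pre_vaf = np.asarray(pre_vaf, dtype=float)
    post_depth = np.asarray(post_depth)
    if np.any(np.asarray(post_depth) < 1):
        raise ValueError("post_depth must be >= 1")
    p = stats.binom.cdf(min_alt - 1, post_depth, pre_vaf)
    return float(p) if p.ndim == 0 else p


def detect_polyclonality(driver_table: pd.DataFrame, polyclonal_min_muts: int = 3) -> int:
    """Count genes carrying a discordant same-gene driver-mutation set.

    A gene contributes iff it carries at least ``polyclonal_min_muts`` distinct
    somatic mutations in the patient and their trajectories are discordant
    (at least one lost and at least one shared or gained).
    """
    if len(driver_table) == 0:
        return 0
    count = 0
    for _, grp in driver_table.groupby("gene"):
        if len(grp) < polyclonal_min_muts:
            continue
        traj = grp["trajectory"]
        if (traj == "pre_only").any() and traj.isin(["shared", "post_only"]).any():
            count += 1
    return count


# ---------------------------------------------------------------------------
# Evolution classification
# ---------------------------------------------------------------------------

@dataclass
class EvolutionThresholds:
    """Explicit stand-ins for the qualitative bottleneck/polyclonal criteria."""

    high_vaf: float = 0.10            # "not at low VAFs"
    lost_fraction_min: float = 0.25   # fraction of high-VAF mutations lost
    shared_min: int = 20              # "non-trivial number shared"
    minor_pre_ccf_max: float = 0.2    # "uncommon clone" before treatment
    minor_post_ccf_min: float = 0.5   # ... expanding after treatment
    # fraction of cluster members detectable pre-treatment: separates genuine
    # minor clones (>= ~0.2 even when diluted by newly arisen mutations) from
    # clusters of wholly new post-treatment mutations (~0.003, error-level)
    minor_pre_detected_min: float = 0.10
    min_cluster_size: int = 3
    detection_floor: float = 0.02
    sampling_alpha: float = 0.01
    polyclonal_min_muts: int = 3
    hypermutator_burden: int = 2000
    cross_spectrum_min: int = 10      # high-VAF losses AND gains for hypermutators


@dataclass
class EvolutionCall:
    patient_id: str
    category: str  # stable | bottleneck | polyclonal | excluded
    metrics: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


def compute_patient_metrics(
    variants: pd.DataFrame,
    clusters: list[CloneCluster],
    thresholds: EvolutionThresholds | None = None,
    drivers=(),
) -> dict:
    """Per-patient evidence metrics from paired retained variants + clusters."""
    th = thresholds or EvolutionThresholds()
    pre_vaf = variants["pre_vaf"].to_numpy(dtype=float)
    post_vaf = variants["post_vaf"].to_numpy(dtype=float)
    post_depth = np.maximum(variants["post_depth"].to_numpy(dtype=float), 1)

    pre_in = pre_vaf >= th.detection_floor
    post_in = post_vaf >= th.detection_floor
    traj = np.where(pre_in & ~post_in, "pre_only", np.where(post_in & ~pre_in, "post_only", "shared"))

    high = pre_vaf >= th.high_vaf
    lost = traj == "pre_only"
    # minimum alt-read count that would have counted as detection post-treatment
    min_alt = np.maximum(1, np.ceil(th.detection_floor * post_depth))
    p_sample = stats.binom.cdf(min_alt - 1, post_depth, np.clip(pre_vaf, 0, 1))
    unexplained_loss = lost & (p_sample < th.sampling_alpha)

    n_high = int(high.sum())
    lost_high_frac = float((unexplained_loss & high).sum() / n_high) if n_high else 0.0
    shared_count = int((pre_in & post_in).sum())

    # an expanding minor clone must have been detectably PRESENT pre-treatment:
    # clusters made purely of post-treatment-only mutations do not qualify
    expanding = False
    for c in clusters:
        if not (c.center_post >= th.minor_post_ccf_min
                and c.center_pre <= th.minor_pre_ccf_max
                and c.size >= th.min_cluster_size):
            continue
        members = variants.loc[np.asarray(c.member_index)]
        det = float((members["pre_vaf"] >= th.detection_floor).mean())
        if det >= th.minor_pre_detected_min:
            expanding = True
            break

    dmask = variants["gene"].isin(set(drivers)) if len(drivers) else pd.Series(False, index=variants.index)
    dtab = pd.DataFrame({"gene": variants.loc[dmask.to_numpy(), "gene"],
                         "trajectory": traj[dmask.to_numpy()]})
    discordant = detect_polyclonality(dtab, th.polyclonal_min_muts)

    burden_pre = int(pre_in.sum())
    cross_loss = int((lost & high).sum())
    cross_gain = int(((traj == "post_only") & (post_vaf >= th.high_vaf)).sum())
    return {
        "lost_high_vaf_fraction": lost_high_frac,
        "shared_count": shared_count,
        "expanding_minor_clone": bool(expanding),
        "discordant_same_gene_drivers": int(discordant),
        "pre_burden": burden_pre,
        "post_burden": int(post_in.sum()),
        "high_vaf_losses": cross_loss,
        "high_vaf_gains": cross_gain,
    }


def classify_evolution(
    metrics: dict,
    qc_excluded: bool = False,
    msi: bool = False,
    thresholds: EvolutionThresholds | None = None,
    patient_id: str = "",
) -> EvolutionCall:
    """Apply the ordered per-patient decision rule (see module docstring)."""
    th = thresholds or EvolutionThresholds()
    if qc_excluded:
        cat = "excluded"
    else:
        hyper = msi or metrics["pre_burden"] >= th.hypermutator_burden
        poly = metrics["discordant_same_gene_drivers"] > 0 or (
            hyper
            and metrics["high_vaf_losses"] >= th.cross_spectrum_min
            and metrics["high_vaf_gains"] >= th.cross_spectrum_min
        )
        if poly:
            cat = "polyclonal"
        elif (
            metrics["lost_high_vaf_fraction"] >= th.lost_fraction_min
            and metrics["shared_count"] >= th.shared_min
            and metrics["expanding_minor_clone"]
        ):
            cat = "bottleneck"
        else:
            cat = "stable"
    return EvolutionCall(patient_id=patient_id, category=cat, metrics=dict(metrics),
                         thresholds=asdict(th))


# ---------------------------------------------------------------------------
# Diversity and spatial concordance
# ---------------------------------------------------------------------------

def vaf_cv(vafs) -> float:
    """Coefficient of variation (sd/mean, ddof=1) of pre-treatment VAFs."""
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 VAFs")
    m = v.mean()
    if m == 0:
        raise ValueError("mean VAF is zero")
    return float(v.std(ddof=1) / m)


def spatial_concordance(sample_a: set, sample_b: set, universe=None, exclude_genes=(),
                        gene_of=None) -> float:
    """Fraction of assessed sites concordantly present or absent in two samples.

    ``universe`` defaults to the union of the two mutation sets.  Sites whose
    gene (via ``gene_of``) is in ``exclude_genes`` are removed first.
    """
    a, b = set(sample_a), set(sample_b)
    sites = set(universe) if universe is not None else a | b
    if exclude_genes and gene_of is not None:
        excl = set(exclude_genes)
        sites = {s for s in sites if gene_of(s) not in excl}
        a, b = a & sites, b & sites
    if not sites:
        raise ValueError("empty assessed-site universe")
    concordant = sum(1 for s in sites if (s in a) == (s in b))
    return concordant / len(sites)
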
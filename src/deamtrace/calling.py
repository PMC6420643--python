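"""Edit calling with a binomial mixture model and barcode encoding.

At each candidate C position the observed C→T read count k out of depth n is
modelled as a two-component binomial mixture

    P(k | n) = pi * Binom(k; n, theta) + (1 - pi) * Binom(k; n, epsilon)

where ``epsilon`` is the background C→T error rate, ``theta`` the allele
fraction of a genuinely edited site and ``pi`` the prior fraction of edited
site/sample observations.  Parameters are estimated by EM.  For unstable
genomes with known ploidy p, the edited component can instead be an
equal-weight mixture over the allele-fraction levels {1/p, 2/p, ..., 1}.

A site/sample observation is called edited when depth > 10, variant allele
count > 2, the posterior probability of the edited component is >= 0.95 and
its allele fraction exceeds the background-control value for that site.

Called edits per sample form the cell barcode, encoded both as a binary
vector over a fixed site ordering and as a CIGAR-like string ("1E10E" = the
1st and 10th ordinal C positions were edited).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

# call thresholds
MIN_DEPTH = 10  # strict: depth must exceed this
MIN_ALT = 2  # strict: alt count must exceed this
MIN_POSTERIOR = 0.95

# site-selection defaults
CORR_THRESHOLD = 0.8  # squared Pearson correlation
SATURATION_EFFICIENCY = 0.8
SATURATION_PROBABILITY = 0.004

# EM settings
EM_TOL = 1e-8
EM_MAX_ITER = 500
EM_INIT = dict(epsilon=0.005, theta=0.5, pi=0.1)
EM_RESTARTS = 3


@dataclass(frozen=True)
class SiteCounts:
    """Depth/alt counts of one site in one sample."""

    site_id: str
    sample_id: str
    depth: int
    alt_count: int
    vaf: float

    @classmethod
    def from_counts(cls, site_id: str, sample_id: str, depth: int, alt_count: int) -> "SiteCounts":
        if alt_count > depth:
            raise ValueError("alt_count exceeds depth")
        vaf = alt_count / depth if depth > 0 else 0.0
        return cls(site_id, sample_id, depth, alt_count, vaf)


@dataclass
class MixtureFit:
    pi: float
    theta: float | tuple[float, ...]
    epsilon: float
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool = False

    def edited_logpmf(self, k: np.ndarray, n: np.ndarray) -> np.ndarray:
        return _edited_logpmf(k, n, self.theta)


@dataclass(frozen=True)
class EditCall:
    site_id: str
    sample_id: str
    posterior: float
    called: bool


@dataclass(frozen=True)
class CellBarcode:
    sample_id: str
    edits: frozenset[str]
    cigar_string: str


def _edited_logpmf(k: np.ndarray, n: np.ndarray, theta) -> np.ndarray:
    """Log density of the edited component (single level or ploidy levels)."""
    if isinstance(theta, (tuple, list, np.ndarray)):
        levels = np.asarray(theta, dtype=float)
        comp = np.stack(
            [stats.binom.logpmf(k, n, lv) for lv in levels], axis=0
        )
        return _logmeanexp(comp)
    return stats.binom.logpmf(k, n, float(theta))


def _logmeanexp(a: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=0) - math.log(a.shape[0])


def _em_once(
    k: np.ndarray,
    n: np.ndarray,
    pi0: float,
    theta0: float,
    eps0: float,
    ploidy_levels: Sequence[float] | None,
) -> MixtureFit:
    pi, theta, eps = pi0, theta0, eps0
    loglik = -np.inf
    for it in range(1, EM_MAX_ITER + 1):
        theta_param = tuple(ploidy_levels) if ploidy_levels else theta
        log_e = _edited_logpmf(k, n, theta_param) + _safe_log(pi)
        log_b = stats.binom.logpmf(k, n, eps) + _safe_log(1.0 - pi)
        m = np.maximum(log_e, log_b)
        denom = m + np.log(np.exp(log_e - m) + np.exp(log_b - m))
        new_loglik = float(denom.sum())
        gamma = np.exp(log_e - denom)
        # M-step
        pi = float(gamma.mean())
        if not ploidy_levels:
            num = float((gamma * k).sum())
            den = float((gamma * n).sum())
            if den > 0:
                theta = min(max(num / den, 1e-9), 1 - 1e-9)
        bnum = float(((1 - gamma) * k).sum())
        bden = float(((1 - gamma) * n).sum())
        if bden > 0:
            eps = min(max(bnum / bden, 1e-9), 1 - 1e-9)
        if abs(new_loglik - loglik) < EM_TOL and it > 1:
            loglik = new_loglik
            return MixtureFit(pi, theta_param, eps, loglik, it, True)
        loglik = new_loglik
    return MixtureFit(pi, theta_param, eps, loglik, EM_MAX_ITER, False)


def _safe_log(x: float) -> float:
    return math.log(max(x, 1e-300))


def fit_mixture(
    counts: Sequence[SiteCounts],
    ploidy_levels: Sequence[float] | None = None,
    seed: int = 0,
) -> MixtureFit:
    """Fit the binomial mixture by EM with seeded restarts.

    Requires >=10 observations with positive depth.  Runs one fit from the
    fixed default initialisation plus ``EM_RESTARTS - 1`` jittered restarts
    and keeps the best log-likelihood.  An all-zero alt profile yields a
    degenerate fit with pi ~ 0 (flagged, not an error).
    """
    obs = [c for c in counts if c.depth > 0]
    if len(obs) < 10:
        raise ValueError("need >=10 sites with positive depth")
    k = np.array([c.alt_count for c in obs], dtype=float)
    n = np.array([c.depth for c in obs], dtype=float)

    if k.sum() == 0:
        fit = _em_once(k, n, 1e-6, EM_INIT["theta"], 1e-6, ploidy_levels)
        fit.degenerate = True
        fit.pi = min(fit.pi, 1e-6)
        return fit

    rng = np.random.default_rng(seed)
    inits = [(EM_INIT["pi"], EM_INIT["theta"], EM_INIT["epsilon"])]
    for _ in range(EM_RESTARTS - 1):
        inits.append(
            (
                float(rng.uniform(0.05, 0.5)),
                float(rng.uniform(0.2, 0.8)),
                float(rng.uniform(1e-4, 0.02)),
            )
        )
    best: MixtureFit | None = None
    for pi0, th0, ep0 in inits:
        fit = _em_once(k, n, pi0, th0, ep0, ploidy_levels)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    # orient components: edited component must have the larger allele fraction
    if not ploidy_levels and best.theta < best.epsilon:
        best.theta, best.epsilon = best.epsilon, best.theta
        best.pi = 1.0 - best.pi
    return best


def posterior_edited(fit: MixtureFit, alt_count: int, depth: int) -> float:
    """Responsibility of the edited component for one (k, n) observation."""
    if depth == 0:
        return 0.0
    k = np.array([float(alt_count)])
    n = np.array([float(depth)])
    log_e = fit.edited_logpmf(k, n) + _safe_log(fit.pi)
    log_b = stats.binom.logpmf(k, n, fit.epsilon) + _safe_log(1.0 - fit.pi)
    m = max(log_e[0], log_b[0])
    return float(np.exp(log_e[0] - m) / (np.exp(log_e[0] - m) + np.exp(log_b[0] - m)))


def call_edits(
    counts: Sequence[SiteCounts],
    fit: MixtureFit,
    control_vafs: Mapping[str, float] | None = None,
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT,
    min_posterior: float = MIN_POSTERIOR,
) -> list[EditCall]:
    """Apply posterior and hard-count thresholds to produce edit calls.

    A missing control VAF for a site is treated as 0, i.e. any positive
    allele fraction exceeds background.
    """
    control_vafs = control_vafs or {}
    calls = []
    for c in counts:
        post = posterior_edited(fit, c.alt_count, c.depth)
        called = (
            c.depth > min_depth
            and c.alt_count > min_alt
            and post >= min_posterior
            and c.vaf > control_vafs.get(c.site_id, 0.0)
        )
        calls.append(EditCall(c.site_id, c.sample_id, post, called))
    return calls


def average_paired_c(a: SiteCounts, b: SiteCounts, target_of: Mapping[str, str] | None = None) -> SiteCounts:
    """Merge the two window Cs of one spacer into a single editing site.

    Deaminase editing is processive across the window, so the paired Cs are
    treated as one site whose efficiency is the mean of the two VAFs.  Depth
    is the conservative minimum of the two depths.  If one position has zero
    depth, the merged VAF falls back to the covered position's VAF.
    """
    if a.sample_id != b.sample_id:
        raise ValueError("paired positions must come from the same sample")
    if target_of is not None and target_of.get(a.site_id) != target_of.get(b.site_id):
        raise ValueError("paired positions must belong to the same target")
    if a.depth == 0 and b.depth == 0:
        vaf = 0.0
    elif a.depth == 0:
        vaf = b.vaf
    elif b.depth == 0:
        vaf = a.vaf
    else:
        vaf = (a.vaf + b.vaf) / 2.0
    depth = min(a.depth, b.depth) if a.depth and b.depth else max(a.depth, b.depth)
    return SiteCounts(
        site_id=f"{a.site_id}|{b.site_id}",
        sample_id=a.sample_id,
        depth=depth,
        alt_count=int(round(vaf * depth)),
        vaf=vaf,
    )


def site_probabilities(efficiency: "np.ndarray | object", site_ids: Sequence[str] | None = None) -> dict[str, float]:
    """Normalise per-site mean editing efficiency to sum to 1 over sites.

    ``efficiency`` is a sites x samples array (or pandas DataFrame indexed by
    site).  The result is each site's contribution to total editing.
    """
    if hasattr(efficiency, "values") and hasattr(efficiency, "index"):
        site_ids = list(efficiency.index)
        mat = np.asarray(efficiency.values, dtype=float)
    else:
        mat = np.asarray(efficiency, dtype=float)
        if site_ids is None:
            site_ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] < 1:
        raise ValueError("need >=1 site")
    means = mat.mean(axis=1)
    total = means.sum()
    if total == 0:
        raise ValueError("all-zero efficiency matrix")
    return {s: float(m / total) for s, m in zip(site_ids, means)}


def filter_sites(
    probabilities: Mapping[str, float],
    efficiency: "object",
    corr_threshold: float = CORR_THRESHOLD,
    saturation_efficiency: float = SATURATION_EFFICIENCY,
    saturation_probability: float = SATURATION_PROBABILITY,
    blacklist: Iterable[str] = (),
) -> list[str]:
    """Select confident sites for lineage reconstruction.

    Removes, in order: (i) blacklisted sites; (ii) near-saturated sites —
    mean efficiency > ``saturation_efficiency`` or normalised site probability
    > ``saturation_probability`` (either alone triggers removal; such sites
    are shared by almost every clone and carry no lineage signal); (iii) one
    site of each highly correlated pair (squared Pearson correlation of
    per-sample efficiencies > ``corr_threshold``), keeping the earlier site
    in the input ordering.
    """
    if hasattr(efficiency, "values") and hasattr(efficiency, "index"):
        site_ids = list(efficiency.index)
        mat = np.asarray(efficiency.values, dtype=float)
    else:
        mat = np.asarray(efficiency, dtype=float)
        site_ids = list(probabilities.keys())
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("efficiency matrix must cover >=2 samples")
    blacklist = set(blacklist)

    keep_idx = []
    for i, s in enumerate(site_ids):
        if s in blacklist:
            continue
        if mat[i].mean() > saturation_efficiency:
            continue
        if probabilities.get(s, 0.0) > saturation_probability:
            continue
        keep_idx.append(i)

    retained: list[int] = []
    for i in keep_idx:
        ok = True
        for j in retained:
            xi, xj = mat[i], mat[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                # constant columns: identical constants are perfectly
                # redundant, otherwise uncorrelated
                r2 = 1.0 if np.allclose(xi, xj) else 0.0
            else:
                r2 = float(np.corrcoef(xi, xj)[0, 1] ** 2)
            if r2 > corr_threshold:
                ok = False
                break
        if ok:
            retained.append(i)
    return [site_ids[i] for i in retained]


_CIGAR_RE = re.compile(r"^(?:\d+E)*$")


def encode_barcode(
    sample_id: str,
    called_sites: Iterable[str],
    site_ordering: Sequence[str],
) -> CellBarcode:
    """Encode a sample's called edits as a CIGAR-like string over site ordinals.

    Ordinal 1 is the first site in ``site_ordering``; "1E10E" means the 1st
    and 10th C positions were edited.
    """
    index = {s: i + 1 for i, s in enumerate(site_ordering)}
    ordinals = []
    for s in called_sites:
        if s not in index:
            raise KeyError(f"unknown site_id {s!r}")
        ordinals.append(index[s])
    ordinals = sorted(set(ordinals))
    cigar = "".join(f"{o}E" for o in ordinals)
    return CellBarcode(
        sample_id=sample_id,
        edits=frozenset(site_ordering[o - 1] for o in ordinals),
        cigar_string=cigar,
    )


def decode_barcode(cigar: str, site_ordering: Sequence[str]) -> frozenset[str]:
    """Inverse of :func:`encode_barcode` on the cigar string."""
    if not _CIGAR_RE.match(cigar):
        raise ValueError(f"malformed barcode string {cigar!r}")
    sites = []
    for num in re.findall(r"(\d+)E", cigar):
        o = int(num)
        if not (1 <= o <= len(site_ordering)):
            raise ValueError(f"ordinal {o} outside site ordering")
        sites.append(site_ordering[o - 1])
    return frozenset(sites)


def binary_vector(barcode: CellBarcode, site_ordering: Sequence[str]) -> np.ndarray:
    """Barcode as a 0/1 vector over the fixed site ordering."""
    return np.array([1 if s in barcode.edits else 0 for s in site_ordering], dtype=np.int8)


def transfer_site_probabilities(
    bulk_probabilities: Mapping[str, float],
    single_cell_sites: Iterable[str],
) -> dict[str, float]:
    """Restrict bulk-derived site probabilities to sites shared with
    single-cell data (bulk and single-cell libraries have different read
    structure, so probabilities are designated on the shared sites only)."""
    shared = set(single_cell_sites)
    return {s: p for s, p in bulk_probabilities.items() if s in shared}
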
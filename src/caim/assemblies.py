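"""PCA-Promax neural-assembly detection and activation statistics.

The detector finds groups of co-activating neurons from z-scored dF/F:

1. significant principal components are those whose correlation-matrix
   eigenvalue exceeds the Marchenko-Pastur upper bound for the data's
   neurons/frames aspect ratio;
2. their loadings are obliquely rotated (Promax, power 4), relaxing PCA's
   orthogonality so a neuron can load on — and belong to — more than one
   assembly;
3. each component's loadings are z-scored and membership is thresholded at
   z_max, chosen automatically as the first local minimum of the smoothed
   distribution of each ROI's maximal z-scored loading (a config override
   reproduces a manual pick);
4. assemblies whose normalized membership-indicator dot product exceeds
   0.6 are merged, greedily, largest dot first;
5. assemblies are kept only if their members are significantly synchronous
   against circular-shift surrogates (p < 0.05).

Activation over time is quantified by the matching index — the proportion
of an assembly's members active in a frame (1 = perfect co-activation) —
with per-frame significance from the exact hypergeometric tail given the
assembly size, population size and number of active neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.multivariate.factor_rotation import promax as _promax_rotation

from .connectivity import stationary_bootstrap_indices

__all__ = [
    "AssemblyModel",
    "ActivationSeries",
    "AssemblyCorrelations",
    "select_significant_pcs",
    "promax_assemblies",
    "membership_dot",
    "merge_assemblies",
    "test_assembly_synchrony",
    "matching_index_series",
    "activation_significance",
    "assembly_assembly_correlation",
    "assembly_speed_correlation",
    "detect_assemblies",
]


@dataclass
class AssemblyModel:
    """Overlapping neuron memberships with loadings and validation state."""

    memberships: list[frozenset[int]]
    loadings: np.ndarray  # neurons x components, z-scored per component
    z_max: float
    n_pcs: int
    n_neurons: int
    merge_log: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    synchrony_p: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_assemblies(self) -> int:
        return len(self.memberships)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.memberships])


@dataclass
class ActivationSeries:
    """Matching-index time series with per-frame significance."""

    matching_index: np.ndarray  # assemblies x frames in [0, 1]
    significant: np.ndarray | None = None  # boolean, same shape
    p_values: np.ndarray | None = None

    @property
    def percent_of_max(self) -> np.ndarray:
        if self.significant is None:
            raise ValueError("significance mask not computed")
        return 100.0 * self.matching_index * self.significant

    def masked(self) -> np.ndarray:
        """Matching index zeroed outside significant activations."""
        if self.significant is None:
            raise ValueError("significance mask not computed")
        return self.matching_index * self.significant


@dataclass
class AssemblyCorrelations:
    """Assembly-assembly and assembly-speed correlation summaries."""

    pair_r: np.ndarray  # assemblies x assemblies, NaN diagonal/undefined
    pair_significant: np.ndarray
    mean_significant_r: float
    speed_r: np.ndarray | None = None
    speed_significant: np.ndarray | None = None

    @property
    def fraction_speed_correlated(self) -> float:
        if self.speed_significant is None:
            raise ValueError("speed correlations not computed")
        ok = np.isfinite(self.speed_r)
        return float(self.speed_significant[ok].mean()) if ok.any() else np.nan


def _effective_frames(z: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size of autocorrelated traces (Bartlett).

    Sample correlations between independent but autocorrelated series have
    variance ~ (1/T) * sum_k rho(k)^2 instead of 1/T, so eigenvalue noise
    behaves as if only T_eff = T / (1 + 2 * sum_{k>0} rho(k)^2) frames were
    seen.  rho is the mean autocorrelation across neurons, estimated by
    FFT and truncated where it first becomes negligible.
    """
    n, T = z.shape
    if max_lag is None:
        max_lag = min(T // 4, 512)
    x = z - z.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, : max_lag + 1]
    rho = (acov / acov[:, :1]).mean(axis=0)
    cut = np.flatnonzero(np.abs(rho) < 2.0 / np.sqrt(T))
    if cut.size:
        rho = rho[: cut[0]]
    factor = 1.0 + 2.0 * float(np.sum(rho[1:] ** 2))
    return T / factor


def select_significant_pcs(z: np.ndarray) -> int:
    """Count eigenvalues above the Marchenko-Pastur upper bound.

    For n neurons over T independent frames of unit-variance data the
    bound is (1 + sqrt(n/T))^2.  Calcium traces are not independent in
    time — the indicator kernel autocorrelates them — so T is replaced by
    the effective frame count implied by the mean autocorrelation
    (temporally white data leaves the bound unchanged).
    """
    z = np.atleast_2d(np.asarray(z, float))
    n, T = z.shape
    if n < 3:
        raise ValueError("need at least 3 neurons")
    c = np.corrcoef(z)
    if not np.all(np.isfinite(c)):
        warnings.warn("degenerate covariance: zero components", stacklevel=2)
        return 0
    eig = np.linalg.eigvalsh(c)
    t_eff = _effective_frames(z)
    bound = (1.0 + np.sqrt(n / t_eff)) ** 2
    return int(np.sum(eig > bound))


def _first_local_minimum(values: np.ndarray) -> float | None:
    """First local minimum of a Gaussian-KDE-smoothed distribution."""
    if values.size < 3 or np.ptp(values) == 0:
        return None
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    d = np.diff(dens)
    for i in range(1, d.size):
        if d[i - 1] < 0 and d[i] >= 0:
            return float(grid[i])
    return None


def promax_assemblies(
    z: np.ndarray,
    n_pcs: int,
    promax_power: int = 4,
    z_max: float | None = None,
    min_members: int = 2,
) -> AssemblyModel:
    """Oblique rotation of significant PC loadings and membership cut.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), Promax-rotated
    (power ``promax_power``), sign-aligned so each component's largest
    absolute loading is positive, and z-scored across neurons.  Membership:
    z-scored loading > z_max.  Components left with fewer than
    ``min_members`` members are dropped (a single neuron is not an
    assembly).
    """
    z = np.atleast_2d(np.asarray(z, float))
    n, T = z.shape
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    c = np.corrcoef(z)
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1][:n_pcs]
    loadings = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0, None))
    if n_pcs > 1:
        try:
            loadings, _ = _promax_rotation(loadings, k=promax_power)
        except Exception as exc:  # non-convergence: surface the components
            raise RuntimeError(f"Promax rotation failed for loadings {loadings!r}") from exc
    # Sign alignment: the dominant loading of each component made positive.
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    zl = (loadings - loadings.mean(axis=0)) / loadings.std(axis=0)

    flags: list[str] = []
    if z_max is None:
        max_per_roi = zl.max(axis=1)
        z_max_auto = _first_local_minimum(max_per_roi)
        if z_max_auto is None:
            z_max_auto = 1.96
            flags.append("z_max fallback (no local minimum found): 1.96")
        z_max = z_max_auto

    memberships = []
    for k in range(zl.shape[1]):
        members = frozenset(np.flatnonzero(zl[:, k] > z_max).tolist())
        if len(members) >= min_members:
            memberships.append(members)
    if not memberships:
        flags.append("no memberships above z_max")
    return AssemblyModel(
        memberships=memberships,
        loadings=zl,
        z_max=float(z_max),
        n_pcs=n_pcs,
        n_neurons=n,
        flags=flags,
    )


def membership_dot(a: frozenset[int], b: frozenset[int]) -> float:
    """Dot product of unit-normalized membership indicator vectors."""
    if not a or not b:
        return 0.0
    return len(a & b) / np.sqrt(len(a) * len(b))


def merge_assemblies(model: AssemblyModel, overlap_threshold: float = 0.6) -> AssemblyModel:
    """Greedily merge assemblies with high membership overlap.

    While any pair of membership indicator vectors (unit-normalized) has a
    dot product above ``overlap_threshold``, the pair with the largest dot
    (ties to the lowest index pair) is unioned.  Merges are logged with
    the original pair indices and their dot product.
    """
    members = list(model.memberships)
    log: list[tuple[tuple[int, int], float]] = []
    while len(members) > 1:
        best, best_pair = 0.0, None
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d = membership_dot(members[i], members[j])
                if d > best + 1e-12:
                    best, best_pair = d, (i, j)
        if best_pair is None or best <= overlap_threshold:
            break
        i, j = best_pair
        log.append(((i, j), best))
        members[i] = members[i] | members[j]
        del members[j]
    return replace(model, memberships=members, merge_log=model.merge_log + log)


def onset_raster(active: np.ndarray) -> np.ndarray:
    """Rising edges of a boolean activity raster (event onsets)."""
    active = np.atleast_2d(np.asarray(active, bool))
    out = active.copy()
    out[:, 1:] &= ~active[:, :-1]
    return out


def _smear(train: np.ndarray, window: int) -> np.ndarray:
    """Mark frames within ``window`` frames after each onset (coincidence)."""
    if window <= 1:
        return train
    out = train.copy()
    for w in range(1, window):
        out[w:] |= train[:-w]
    return out


def test_assembly_synchrony(
    model: AssemblyModel,
    raster: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
    window_frames: int = 3,
) -> AssemblyModel:
    """Keep assemblies whose peak onset coincidence beats circular surrogates.

    The statistic is the maximal number of members with a transient onset
    inside any ``window_frames`` coincidence window (onsets, not whole
    transients, carry the synchrony: the slow indicator decay would
    otherwise saturate the statistic).  Each surrogate independently
    circularly shifts every member's onset train, preserving rates while
    destroying synchrony.  p = (1 + #{surrogate >= observed}) /
    (n_surrogates + 1); assemblies with p >= ``p_threshold`` are dropped.

    ``raster`` may be a boolean activity raster; onsets are its rising
    edges.
    """
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates: coarse p-values", stacklevel=2)
    onsets = onset_raster(raster)
    T = onsets.shape[1]
    rng = np.random.default_rng(seed)
    base = np.arange(T)
    kept, pvals = [], []
    all_p = np.full(model.n_assemblies, np.nan)
    for a, members in enumerate(model.memberships):
        idx = np.fromiter(members, dtype=int)
        smeared = np.vstack([_smear(onsets[i], window_frames) for i in idx])
        obs = int(smeared.sum(axis=0).max())
        counts = np.zeros((n_surrogates, T), dtype=np.int16)
        for row in smeared:
            shifts = rng.integers(T, size=n_surrogates)
            counts += row[(base[None, :] - shifts[:, None]) % T]
        p = (1.0 + np.sum(counts.max(axis=1) >= obs)) / (n_surrogates + 1.0)
        all_p[a] = p
        if p < p_threshold:
            kept.append(members)
            pvals.append(p)
    flags = list(model.flags)
    dropped = model.n_assemblies - len(kept)
    if dropped:
        flags.append(f"{dropped} assembly(ies) failed the synchrony test")
    return replace(
        model, memberships=kept, synchrony_p=np.asarray(pvals), flags=flags
    )


def matching_index_series(raster: np.ndarray, memberships) -> ActivationSeries:
    """Per-frame proportion of each assembly's members that are active."""
    raster = np.atleast_2d(np.asarray(raster, bool))
    if any(len(m) == 0 for m in memberships):
        raise ValueError("memberships must be non-empty")
    mi = np.vstack(
        [raster[np.fromiter(m, dtype=int)].mean(axis=0) for m in memberships]
    )
    return ActivationSeries(matching_index=mi)


def activation_significance(
    raster: np.ndarray,
    memberships,
    p_threshold: float = 0.05,
) -> ActivationSeries:
    """Hypergeometric per-frame significance of assembly activations.

    With m of N neurons active in a frame, the chance of >= k of them
    falling inside an assembly of size K is the hypergeometric upper tail
    P(X >= k | N, K, m).  A frame is a significant activation when that
    tail probability is below ``p_threshold`` (and k >= 1).
    """
    raster = np.atleast_2d(np.asarray(raster, bool))
    N, T = raster.shape
    m = raster.sum(axis=0)  # active population per frame
    series = matching_index_series(raster, memberships)
    n_a = len(memberships)
    p = np.ones((n_a, T))
    for a, members in enumerate(memberships):
        K = len(members)
        k = np.rint(series.matching_index[a] * K).astype(int)
        p[a] = stats.hypergeom.sf(k - 1, N, K, m)
    significant = (p < p_threshold) & (series.matching_index > 0)
    series.p_values = p
    series.significant = significant
    return series


def _pearson_pairs(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r with NaN for zero-variance rows."""
    n = x.shape[0]
    r = np.full((n, n), np.nan)
    ok = x.std(axis=1) > 0
    if ok.sum() >= 2:
        r[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    np.fill_diagonal(r, np.nan)
    return r


def _bootstrap_pair_significance(
    x: np.ndarray,
    y: np.ndarray,
    r_obs: float,
    n_iterations: int,
    mean_block_frames: float,
    quantile: float,
    rng: np.random.Generator,
) -> bool:
    """Stationary-bootstrap significance for one series pair."""
    T = x.size
    xs = (x - x.mean()) / x.std()
    null = np.empty(n_iterations)
    for b in range(n_iterations):
        idx = stationary_bootstrap_indices(T, mean_block_frames, rng)
        yb = y[idx]
        sd = yb.std()
        if sd == 0:
            null[b] = 0.0
            continue
        null[b] = float(xs @ ((yb - yb.mean()) / sd)) / T
    return r_obs > np.quantile(null, quantile)


def assembly_assembly_correlation(
    series: ActivationSeries,
    n_iterations: int = 1000,
    mean_block_frames: float = 23.0,
    quantile: float = 0.99,
    seed: int = 0,
) -> AssemblyCorrelations:
    """Correlations between significance-masked activation series.

    Pearson r between each pair of masked matching-index series, with
    stationary-bootstrap significance per pair (one member resampled).
    ``mean_significant_r`` averages only significant pairs, the same
    exclusion applied to non-significant r values in the source workflow.
    """
    masked = series.masked()
    n_a = masked.shape[0]
    if n_a < 2:
        raise ValueError("need at least 2 assemblies")
    r = _pearson_pairs(masked)
    sig = np.zeros_like(r, dtype=bool)
    rng = np.random.default_rng(seed)
    for i in range(n_a):
        for j in range(i + 1, n_a):
            if not np.isfinite(r[i, j]):
                continue
            s = _bootstrap_pair_significance(
                masked[i], masked[j], r[i, j], n_iterations, mean_block_frames, quantile, rng
            )
            sig[i, j] = sig[j, i] = s
    iu = np.triu_indices(n_a, k=1)
    sel = sig[iu] & np.isfinite(r[iu])
    mean_r = float(r[iu][sel].mean()) if sel.any() else np.nan
    return AssemblyCorrelations(pair_r=r, pair_significant=sig, mean_significant_r=mean_r)


def assembly_speed_correlation(
    series: ActivationSeries,
    speed: np.ndarray,
    n_iterations: int = 1000,
    mean_block_frames: float = 23.0,
    quantile: float = 0.995,
    seed: int = 0,
) -> AssemblyCorrelations:
    """Correlation of masked activations with animal speed, per assembly.

    Two-sided at the bootstrap level: |r| is compared with the ``quantile``
    of the null |r| (default 0.995, i.e. alpha = 0.01 two-sided).
    Constant series (either side) yield NaN and are flagged undefined.
    """
    masked = series.masked()
    speed = np.asarray(speed, float)
    if speed.size != masked.shape[1]:
        raise ValueError("speed and activation series must be aligned")
    n_a = masked.shape[0]
    r = np.full(n_a, np.nan)
    sig = np.zeros(n_a, dtype=bool)
    rng = np.random.default_rng(seed)
    if speed.std() > 0:
        ss = (speed - speed.mean()) / speed.std()
        T = speed.size
        for a in range(n_a):
            x = masked[a]
            if x.std() == 0:
                continue
            r[a] = float(np.corrcoef(x, speed)[0, 1])
            null = np.empty(n_iterations)
            xs = (x - x.mean()) / x.std()
            for b in range(n_iterations):
                idx = stationary_bootstrap_indices(T, mean_block_frames, rng)
                xb = xs[idx]
                sd = xb.std()
                null[b] = abs(float((xb - xb.mean()) @ ss) / T / sd) if sd > 0 else 0.0
            sig[a] = abs(r[a]) > np.quantile(null, quantile)
    return AssemblyCorrelations(
        pair_r=np.full((n_a, n_a), np.nan),
        pair_significant=np.zeros((n_a, n_a), dtype=bool),
        mean_significant_r=np.nan,
        speed_r=r,
        speed_significant=sig,
    )


def detect_assemblies(
    z: np.ndarray,
    raster: np.ndarray,
    promax_power: int = 4,
    z_max: float | None = None,
    overlap_threshold: float = 0.6,
    n_surrogates: int = 1000,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> AssemblyModel:
    """Full chain: PC count, Promax rotation, merge, synchrony validation."""
    n_pcs = select_significant_pcs(z)
    if n_pcs == 0:
        n = np.atleast_2d(z).shape[0]
        return AssemblyModel(
            memberships=[],
            loadings=np.empty((n, 0)),
            z_max=np.nan,
            n_pcs=0,
            n_neurons=n,
            flags=["no significant principal components"],
        )
    model = promax_assemblies(z, n_pcs, promax_power=promax_power, z_max=z_max)
    model = merge_assemblies(model, overlap_threshold=overlap_threshold)
    return test_assembly_synchrony(
        model, raster, n_surrogates=n_surrogates, seed=seed, p_threshold=p_threshold
    )
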
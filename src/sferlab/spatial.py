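"""Event-table-level spatial analytics for one-photon calcium imaging.

Operates on a session "scene": a 20 Hz trajectory with lap labels plus a
binary calcium-event table, binned onto a 48 x 48 grid of 2 cm bins
(optionally with maze walls).  Provides rate maps with wall-aware
Gaussian smoothing, Skaggs spatial information, the three place-cell
shuffle tests, place-field identification with saddle splitting,
within-session stability, signal-to-noise, field-statistics
distribution fits, and a naive Bayes position decoder with a
distance-based loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, lognorm, nbinom, pearsonr

__all__ = [
    "SessionScene", "RateMap", "PlaceField",
    "binarize_events", "compute_rate_map", "spatial_information",
    "place_cell_tests", "identify_fields", "within_session_stability",
    "snr", "field_statistics_fits", "bayes_decode", "cross_session_decode",
    "synthetic_scene",
]

FPS = 20.0
BIN_CM = 2.0
GRID = 48
MIN_OCCUPANCY_S = 0.05
SPEED_MIN_CMS = 2.5
RATE_THRESHOLD_HZ = 0.2
SPLIT_RATIO = 0.5


@dataclass
class SessionScene:
    positions: np.ndarray            # (T, 2) cm
    events: np.ndarray               # (n_cells, T) binary
    speeds: np.ndarray | None = None
    laps: np.ndarray | None = None
    n_bins: int = GRID
    bin_cm: float = BIN_CM
    fps: float = FPS
    # wall_right[r, c]: wall between bin (r, c) and (r, c+1); analogous down
    wall_right: np.ndarray | None = None
    wall_down: np.ndarray | None = None
    truth: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.events = np.asarray(self.events)
        if self.events.shape[1] != self.positions.shape[0]:
            raise ValueError("events and positions must share the frame axis")
        if self.speeds is None:
            d = np.diff(self.positions, axis=0, prepend=self.positions[:1])
            self.speeds = np.linalg.norm(d, axis=1) * self.fps
        if self.laps is None:
            self.laps = np.zeros(len(self.positions), dtype=int)
        self._dist = None

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    def bin_of_frame(self) -> np.ndarray:
        """Flat (row-major) bin index per frame."""
        ij = np.clip((self.positions / self.bin_cm).astype(int), 0, self.n_bins - 1)
        return ij[:, 1] * self.n_bins + ij[:, 0]

    def valid_frames(self) -> np.ndarray:
        return self.speeds >= SPEED_MIN_CMS

    def distance_matrix(self, metric: str = "geodesic") -> np.ndarray:
        """Pairwise bin-center distances in cm (geodesic respects walls)."""
        n = self.n_bins
        if metric == "euclidean":
            r, c = np.divmod(np.arange(n * n), n)
            dx = c[:, None] - c[None, :]
            dy = r[:, None] - r[None, :]
            return np.hypot(dx, dy) * self.bin_cm
        if self._dist is None:
            self._dist = _geodesic_distances(n, self.wall_right, self.wall_down) \
                * self.bin_cm
        return self._dist


def _geodesic_distances(n: int, wall_right, wall_down) -> np.ndarray:
    """All-pairs shortest-path bin distances on the 4-connected grid with
    walls removed from the adjacency."""
    idx = np.arange(n * n).reshape(n, n)
    rows, cols = [], []
    right_ok = np.ones((n, n - 1), dtype=bool)
    down_ok = np.ones((n - 1, n), dtype=bool)
    if wall_right is not None:
        right_ok &= ~np.asarray(wall_right, bool)[:, : n - 1]
    if wall_down is not None:
        down_ok &= ~np.asarray(wall_down, bool)[: n - 1, :]
    r_src = idx[:, :-1][right_ok]
    r_dst = idx[:, 1:][right_ok]
    d_src = idx[:-1, :][down_ok]
    d_dst = idx[1:, :][down_ok]
    rows = np.concatenate([r_src, d_src])
    cols = np.concatenate([r_dst, d_dst])
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n * n, n * n))
    return shortest_path(graph, method="D", directed=False, unweighted=True)


@dataclass
class RateMap:
    occupancy_s: np.ndarray          # per bin
    raw_rate: np.ndarray             # Hz, NaN on invalid bins
    smoothed_rate: np.ndarray        # Hz, NaN on invalid bins
    valid: np.ndarray                # occupancy >= 50 ms
    n_bins: int


@dataclass
class PlaceField:
    bins: np.ndarray                 # flat bin indices
    peak_rate: float
    center_bin: int
    n_events: int = 0
    n_laps: int = 0


def binarize_events(deconvolved: np.ndarray, speeds=None,
                    sd_factor: float = 3.0,
                    speed_min: float = SPEED_MIN_CMS) -> np.ndarray:
    """Calcium events: deconvolved value above sd_factor * SD per cell;
    frames slower than speed_min cm/s are discarded (set to 0)."""
    deconvolved = np.atleast_2d(np.asarray(deconvolved, dtype=float))
    if deconvolved.size == 0:
        raise ValueError("empty traces")
    sd = deconvolved.std(axis=1, keepdims=True)
    ev = (deconvolved > sd_factor * sd) & (sd > 0)
    if speeds is not None:
        ev = ev & (np.asarray(speeds) >= speed_min)[None, :]
    return ev.astype(np.uint8)


def _smoothing_weights(scene: SessionScene, sigma_bins: float = 2.0) -> np.ndarray:
    d = scene.distance_matrix("geodesic") / scene.bin_cm  # bin units
    with np.errstate(over="ignore"):
        w = np.exp(-0.5 * (d / sigma_bins) ** 2)
    w[~np.isfinite(d)] = 0.0   # unreachable across walls: no mass transfer
    return w


def compute_rate_map(scene: SessionScene, cell: int,
                     sigma_bins: float = 2.0, frames=None) -> RateMap:
    """Event rate per 2 cm bin with wall-aware Gaussian smoothing.

    The smoothing kernel is a Gaussian in geodesic (in-maze) distance,
    renormalized per bin over the reachable valid bins, so no rate mass
    crosses a wall.  Bins occupied for less than 50 ms are invalid.
    """
    nb = scene.n_bins * scene.n_bins
    use = scene.valid_frames()
    if frames is not None:
        use = use & frames
    bins = scene.bin_of_frame()[use]
    if len(bins) == 0:
        raise ValueError("no usable frames (zero occupancy everywhere)")
    occ = np.bincount(bins, minlength=nb) / scene.fps
    ev = np.bincount(bins, weights=scene.events[cell, use], minlength=nb)
    valid = occ >= MIN_OCCUPANCY_S
    raw = np.full(nb, np.nan)
    raw[valid] = ev[valid] / occ[valid]

    W = _smoothing_weights(scene, sigma_bins)
    sm = np.full(nb, np.nan)
    vw = W[:, valid]
    denom = vw.sum(axis=1)
    ok = denom > 0
    sm[valid & ok] = (vw @ raw[valid])[valid & ok] / denom[valid & ok]
    return RateMap(occupancy_s=occ, raw_rate=raw, smoothed_rate=sm,
                   valid=valid, n_bins=scene.n_bins)


def spatial_information(rate_map: RateMap, use_smoothed: bool = True) -> float:
    """Skaggs spatial information in bits per event:
    SI = (1/lam) * sum_i lam_i * log2(lam_i / lam) * P_i over valid bins."""
    rate = rate_map.smoothed_rate if use_smoothed else rate_map.raw_rate
    v = rate_map.valid & np.isfinite(rate)
    occ = rate_map.occupancy_s[v]
    lam_i = rate[v]
    P = occ / occ.sum()
    lam = float(np.sum(lam_i * P))
    if lam <= 0:
        raise ValueError("mean rate is zero")
    ratio = lam_i / lam
    terms = np.where(lam_i > 0, lam_i * np.log2(np.maximum(ratio, 1e-300)) * P, 0.0)
    return float(terms.sum() / lam)


def _si_of_events(scene, cell, events_row, frames_mask, W, prec):
    """SI from a replacement event row, reusing precomputed occupancy."""
    bins, occ, valid, denomW = prec
    nb = scene.n_bins * scene.n_bins
    ev = np.bincount(bins, weights=events_row[frames_mask], minlength=nb)
    raw = np.full(nb, np.nan)
    raw[valid] = ev[valid] / occ[valid]
    smv = (W[:, valid][valid] @ raw[valid]) / denomW
    occv = occ[valid]
    P = occv / occv.sum()
    lam = float(np.sum(smv * P))
    if lam <= 0:
        return 0.0
    return float(np.sum(np.where(smv > 0,
                                 smv * np.log2(np.maximum(smv / lam, 1e-300)) * P,
                                 0.0)) / lam)


def place_cell_tests(scene: SessionScene, cell: int, n_shuffles: int = 1000,
                     seed: int | None = None, min_shift_s: float = 20.0,
                     percentile: float = 95.0) -> dict:
    """Three shuffle tests for place coding.

    1) temporal shift: circular shift of the event train by >= 20 s;
    2) inter-event-interval shuffle: event train rebuilt from permuted
       inter-event intervals;
    3) random shuffle: events placed at random usable frames.
    A cell passes when its real spatial information exceeds the given
    percentile of every null (each run ``n_shuffles`` times).
    """
    rng = np.random.default_rng(seed)
    use = scene.valid_frames()
    T = scene.events.shape[1]
    ev_row = scene.events[cell].astype(float)
    if ev_row[use].sum() < 2:
        raise ValueError("too few events for shuffle tests")

    nb = scene.n_bins * scene.n_bins
    bins = scene.bin_of_frame()[use]
    occ = np.bincount(bins, minlength=nb) / scene.fps
    valid = occ >= MIN_OCCUPANCY_S
    W = _smoothing_weights(scene)
    denomW = W[:, valid][valid].sum(axis=1)
    prec = (bins, occ, valid, denomW)

    real = _si_of_events(scene, cell, ev_row, use, W, prec)
    min_shift = int(min_shift_s * scene.fps)
    ev_idx = np.flatnonzero(ev_row)
    intervals = np.diff(ev_idx) if len(ev_idx) > 1 else np.array([1])
    usable = np.flatnonzero(use)
    n_ev = int(ev_row[use].sum())

    nulls = {"temporal_shift": np.empty(n_shuffles),
             "interval_shuffle": np.empty(n_shuffles),
             "random_shuffle": np.empty(n_shuffles)}
    for k in range(n_shuffles):
        shift = int(rng.integers(min_shift, T - min_shift)) if T > 2 * min_shift \
            else int(rng.integers(1, T))
        nulls["temporal_shift"][k] = _si_of_events(
            scene, cell, np.roll(ev_row, shift), use, W, prec)

        perm = rng.permutation(intervals)
        start = ev_idx[0] if len(ev_idx) else 0
        new_idx = (start + np.concatenate([[0], np.cumsum(perm)])) % T
        row = np.zeros(T)
        row[new_idx.astype(int)] = 1.0
        nulls["interval_shuffle"][k] = _si_of_events(scene, cell, row, use, W, prec)

        row = np.zeros(T)
        row[rng.choice(usable, size=min(n_ev, len(usable)), replace=False)] = 1.0
        nulls["random_shuffle"][k] = _si_of_events(scene, cell, row, use, W, prec)

    pct = {name: float(np.mean(real > null) * 100) for name, null in nulls.items()}
    passed = all(real > np.percentile(null, percentile) for null in nulls.values())
    return {"si": real, "percentiles": pct, "passed": bool(passed), "nulls": nulls}


def identify_fields(rate_map: RateMap, event_bins=None, lap_of_event=None,
                    rate_threshold: float = RATE_THRESHOLD_HZ,
                    min_events: int = 5, min_laps: int = 5,
                    split_ratio: float = SPLIT_RATIO) -> list[PlaceField]:
    """Connected supra-threshold components, split at deep saddles.

    Candidate bins have smoothed rate above the threshold (0.2 Hz); a
    field needs at least ``min_events`` events and activity in at least
    ``min_laps`` laps (checks skipped when the corresponding inputs are
    None).  Adjacent peaks within a component are split into separate
    fields when the saddle-to-peak ratio falls below ``split_ratio``.
    """
    n = rate_map.n_bins
    rate = np.nan_to_num(rate_map.smoothed_rate, nan=0.0).reshape(n, n)
    above = rate > rate_threshold
    labels, n_comp = ndimage.label(above)
    fields = []
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        for sub in _split_component(rate, mask, split_ratio):
            flat = np.flatnonzero(sub.ravel())
            peak = float(rate.ravel()[flat].max())
            center = int(flat[np.argmax(rate.ravel()[flat])])
            ne, nl = 0, 0
            if event_bins is not None:
                inside = np.isin(event_bins, flat)
                ne = int(inside.sum())
                if ne < min_events:
                    continue
                if lap_of_event is not None:
                    nl = len(np.unique(np.asarray(lap_of_event)[inside]))
                    if nl < min_laps:
                        continue
            fields.append(PlaceField(bins=flat, peak_rate=peak, center_bin=center,
                                     n_events=ne, n_laps=nl))
    return fields


def _split_component(rate: np.ndarray, mask: np.ndarray, split_ratio: float):
    """Watershed a component at its local maxima; merge basins whose
    saddle-to-peak ratio exceeds the split threshold."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    vals = np.where(mask, rate, 0.0)
    peaks = peak_local_max(vals, labels=mask.astype(int), min_distance=1,
                           exclude_border=False)
    if len(peaks) <= 1:
        return [mask]
    markers = np.zeros_like(mask, dtype=int)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    basins = watershed(-vals, markers=markers, mask=mask)
    k = len(peaks)
    peak_val = {i + 1: rate[tuple(peaks[i])] for i in range(k)}
    # saddle between basins a, b: highest rate on their contact boundary
    saddle = {}
    for ax, shift in ((0, 1), (1, 1)):
        a = basins[tuple(slice(None, -1) if i == ax else slice(None) for i in range(2))]
        b = basins[tuple(slice(1, None) if i == ax else slice(None) for i in range(2))]
        ra = vals[tuple(slice(None, -1) if i == ax else slice(None) for i in range(2))]
        rb = vals[tuple(slice(1, None) if i == ax else slice(None) for i in range(2))]
        touching = (a > 0) & (b > 0) & (a != b)
        for i, j, va, vb in zip(a[touching], b[touching], ra[touching], rb[touching]):
            key = (min(i, j), max(i, j))
            saddle[key] = max(saddle.get(key, 0.0), min(va, vb))
    # union-find merge when saddle / lower peak > split threshold
    parent = list(range(k + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged = True
    while merged:
        merged = False
        for (i, j), s in saddle.items():
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            lower_peak = min(max(peak_val[l] for l in range(1, k + 1) if find(l) == ri),
                             max(peak_val[l] for l in range(1, k + 1) if find(l) == rj))
            if lower_peak > 0 and s / lower_peak > split_ratio:
                parent[max(ri, rj)] = min(ri, rj)
                merged = True
    groups = {}
    for l in range(1, k + 1):
        groups.setdefault(find(l), []).append(l)
    return [np.isin(basins, g) for g in groups.values()]


def within_session_stability(scene: SessionScene, cell: int,
                             field_bins=None, min_field_bins: int = 16) -> float:
    """Pearson correlation of smoothed rate maps between the first and
    second half of laps; the within-field variant restricts to the field
    bins, padded with surrounding bins up to a minimum of 16."""
    laps = scene.laps
    uniq = np.unique(laps)
    half = len(uniq) // 2
    first = np.isin(laps, uniq[:half])
    second = np.isin(laps, uniq[half:])
    m1 = compute_rate_map(scene, cell, frames=first)
    m2 = compute_rate_map(scene, cell, frames=second)
    v = m1.valid & m2.valid & np.isfinite(m1.smoothed_rate) & \
        np.isfinite(m2.smoothed_rate)
    if field_bins is not None:
        sel = np.zeros_like(v)
        sel[np.asarray(field_bins, int)] = True
        if sel.sum() < min_field_bins:
            d = scene.distance_matrix("geodesic")
            center = np.asarray(field_bins, int)[0]
            order = np.argsort(d[center])
            for b in order:
                sel[b] = True
                if sel.sum() >= min_field_bins:
                    break
        v = v & sel
    if v.sum() < 3:
        raise ValueError("no overlapping valid bins between halves")
    r, _ = pearsonr(m1.smoothed_rate[v], m2.smoothed_rate[v])
    return float(r)


def snr(trace: np.ndarray, baseline_fraction: float = 0.75) -> float:
    """Signal-to-noise: max(dF/F) over the SD of the lowest 75% of values."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 4:
        raise ValueError("trace too short")
    k = max(int(np.floor(baseline_fraction * trace.size)), 2)
    baseline = np.sort(trace)[:k]
    sd = baseline.std()
    if sd == 0:
        raise ValueError("zero baseline variability; SNR undefined")
    return float(trace.max() / sd)


def _lilliefors_pvalue(data, dist_name, B: int = 200, seed=None) -> dict:
    """Parametric-bootstrap (Lilliefors-corrected) KS test: parameters are
    re-estimated on every bootstrap sample drawn from the fitted law."""
    rng = np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)
    n = len(data)

    def fit_and_stat(x):
        if dist_name == "lognorm":
            s, loc, sc = lognorm.fit(x, floc=0)
            return (s, loc, sc), kstest(x, "lognorm", args=(s, loc, sc)).statistic
        if dist_name == "gamma":
            a, loc, sc = gamma_dist.fit(x, floc=0)
            return (a, loc, sc), kstest(x, "gamma", args=(a, loc, sc)).statistic
        if dist_name == "nbinom":
            mu, var = x.mean(), x.var()
            var = max(var, mu + 1e-9)
            p = mu / var
            r = mu * p / (1 - p)
            stat = kstest(x, lambda q: nbinom.cdf(np.floor(q), r, p)).statistic
            return (r, p), stat
        raise ValueError(dist_name)

    params, stat = fit_and_stat(data)
    null = np.empty(B)
    for b in range(B):
        if dist_name == "lognorm":
            sample = lognorm.rvs(*params, size=n, random_state=rng)
        elif dist_name == "gamma":
            sample = gamma_dist.rvs(*params, size=n, random_state=rng)
        else:
            sample = nbinom.rvs(*params, size=n, random_state=rng)
        _, null[b] = fit_and_stat(sample)
    p = (1 + np.sum(null >= stat)) / (1 + B)
    return {"params": params, "statistic": float(stat), "p_value": float(p)}


def field_statistics_fits(field_sizes=None, field_counts=None,
                          size_downsample: int = 1621, count_downsample: int = 500,
                          B: int = 200, seed: int | None = None) -> dict:
    """Distribution fits for field sizes (lognormal and gamma) and per-
    neuron field counts (negative binomial), with Lilliefors-corrected KS
    via parametric bootstrap after downsampling to the reference sample
    sizes (1621 sizes, 500 counts)."""
    rng = np.random.default_rng(seed)
    out = {}
    if field_sizes is not None:
        x = np.asarray(field_sizes, dtype=float)
        if len(x) < 10:
            raise ValueError("too few field sizes")
        if len(x) > size_downsample:
            x = rng.choice(x, size_downsample, replace=False)
        out["sizes_lognormal"] = _lilliefors_pvalue(x, "lognorm", B, rng.integers(2**31))
        out["sizes_gamma"] = _lilliefors_pvalue(x, "gamma", B, rng.integers(2**31))
    if field_counts is not None:
        x = np.asarray(field_counts, dtype=float)
        if len(x) < 10:
            raise ValueError("too few field counts")
        if len(x) > count_downsample:
            x = rng.choice(x, count_downsample, replace=False)
        out["counts_negbinom"] = _lilliefors_pvalue(x, "nbinom", B, rng.integers(2**31))
    if not out:
        raise ValueError("provide field sizes and/or counts")
    return out


# ----------------------------------------------------------------- decoding

def _bernoulli_model(scene: SessionScene, cells, frames) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell per-bin event probabilities and bin prior from training frames."""
    nb = scene.n_bins * scene.n_bins
    use = scene.valid_frames() & frames
    bins = scene.bin_of_frame()[use]
    occ = np.bincount(bins, minlength=nb).astype(float)
    prior = occ / occ.sum()
    probs = np.empty((len(cells), nb))
    for k, c in enumerate(cells):
        ev = np.bincount(bins, weights=scene.events[c, use].astype(float),
                         minlength=nb)
        with np.errstate(invalid="ignore"):
            p = np.where(occ > 0, ev / np.maximum(occ, 1), 0.0)
        probs[k] = np.clip(p, 1e-4, 1 - 1e-4)
    return probs, prior


def _decode_frames(scene, probs, prior, cells, frames, D) -> np.ndarray:
    """Distance-loss decoding: argmin_yhat sum_y D[yhat, y] * p_t(y)."""
    use = np.flatnonzero(scene.valid_frames() & frames)
    ev = scene.events[np.asarray(cells)][:, use].astype(float)
    logp = np.log(probs)
    log1p = np.log1p(-probs)
    with np.errstate(divide="ignore"):
        logprior = np.where(prior > 0, np.log(prior), -np.inf)
    ll = ev.T @ logp + (1 - ev).T @ log1p + logprior[None, :]
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    Dfin = np.where(np.isfinite(D), D, np.nanmax(D[np.isfinite(D)]) * 2)
    exp_loss = post @ Dfin.T
    return use, np.argmin(exp_loss, axis=1)


def bayes_decode(scene: SessionScene, cells=None, train_lap_fraction: float = 0.6,
                 metric: str = "geodesic", seed: int | None = None) -> dict:
    """Naive Bayes position decoding with a distance loss, cross-validated
    by rolling the training laps.

    Returns per-lap median absolute decoding errors (cm) and their
    overall median.
    """
    cells = np.arange(scene.n_cells) if cells is None else np.asarray(cells)
    laps = scene.laps
    uniq = np.unique(laps)
    if len(uniq) < 2:
        raise ValueError("need at least two laps for cross-validation")
    n_train = max(int(round(train_lap_fraction * len(uniq))), 1)
    D = scene.distance_matrix(metric)
    true_bins = scene.bin_of_frame()
    lap_errors = {}
    for start in range(len(uniq)):
        train_laps = uniq[(np.arange(n_train) + start) % len(uniq)]
        test_laps = np.setdiff1d(uniq, train_laps)
        train_frames = np.isin(laps, train_laps)
        probs, prior = _bernoulli_model(scene, cells, train_frames)
        for lap in test_laps:
            if lap in lap_errors:
                continue
            test_frames = laps == lap
            if not (scene.valid_frames() & test_frames).any():
                continue
            idx, decoded = _decode_frames(scene, probs, prior, cells,
                                          test_frames, D)
            err = D[decoded, true_bins[idx]]
            lap_errors[int(lap)] = float(np.median(err))
        if len(lap_errors) == len(uniq):
            break
    med = float(np.median(list(lap_errors.values())))
    return {"lap_median_error_cm": lap_errors, "median_error_cm": med}


def cross_session_decode(scene_train: SessionScene, scene_test: SessionScene,
                         shared_cells_train, shared_cells_test,
                         n_subsample: int = 100, n_repeats: int = 5,
                         metric: str = "geodesic",
                         seed: int | None = None) -> dict:
    """Train on one session, decode another through registered neurons.

    Registered cells are randomly downsampled to 100 (all of them, with a
    warning, when fewer are shared); the loss is averaged over 5
    resamples.
    """
    import warnings

    tr = np.asarray(shared_cells_train)
    te = np.asarray(shared_cells_test)
    if len(tr) != len(te):
        raise ValueError("shared cell lists must align")
    rng = np.random.default_rng(seed)
    if len(tr) < n_subsample:
        warnings.warn(f"only {len(tr)} shared neurons; using all", stacklevel=2)
        n_subsample = len(tr)
        n_repeats = 1
    D = scene_test.distance_matrix(metric)
    true_bins = scene_test.bin_of_frame()
    losses = []
    all_frames_train = np.ones(scene_train.events.shape[1], dtype=bool)
    all_frames_test = np.ones(scene_test.events.shape[1], dtype=bool)
    for _ in range(n_repeats):
        pick = rng.choice(len(tr), n_subsample, replace=False)
        probs, prior = _bernoulli_model(scene_train, tr[pick], all_frames_train)
        idx, decoded = _decode_frames(scene_test, probs, prior, te[pick],
                                      all_frames_test, D)
        losses.append(float(np.median(D[decoded, true_bins[idx]])))
    return {"mean_loss_cm": float(np.mean(losses)), "losses": losses}


# ----------------------------------------------------------------- fixtures

def synthetic_scene(n_cells: int = 12, n_frames: int = 6000, n_fields_per_cell=1,
                    field_sigma_cm: float = 6.0, peak_rate_hz: float = 4.0,
                    baseline_rate_hz: float = 0.02, n_bins: int = GRID,
                    n_laps: int = 10, rng=None) -> SessionScene:
    """Synthetic open-arena scene with planted Gaussian place fields.

    A boustrophedon trajectory sweeps the arena ``n_laps`` times; each
    cell emits Poisson events modulated by its planted field(s).  Ground
    truth (field centers, per-cell rates) rides along in ``truth``.
    """
    rng = np.random.default_rng() if rng is None else rng
    size = n_bins * BIN_CM
    t = np.arange(n_frames)
    lap_len = n_frames // n_laps
    frac = (t % lap_len) / lap_len          # progress within the lap
    # each lap is a full boustrophedon sweep: y rises 0 -> size while x
    # zigzags across the arena many times
    n_zigzag = max(n_bins // 3, 4)
    x = np.abs(2 * ((frac * n_zigzag) % 1.0) - 1) * (size - 1e-6)
    y = frac * (size - 1e-6)
    jitter = rng.normal(0, 0.5, (n_frames, 2))
    pos = np.clip(np.stack([x, y], axis=1) + jitter, 0, size - 1e-6)
    laps = np.minimum(t // lap_len, n_laps - 1).astype(int)

    centers = rng.uniform(4, size - 4, (n_cells, int(np.max(np.atleast_1d(n_fields_per_cell))), 2))
    events = np.zeros((n_cells, n_frames), dtype=np.uint8)
    nf = np.broadcast_to(np.atleast_1d(n_fields_per_cell), (n_cells,))
    for c in range(n_cells):
        rate = np.full(n_frames, baseline_rate_hz)
        for f in range(nf[c]):
            d2 = np.sum((pos - centers[c, f]) ** 2, axis=1)
            rate = rate + peak_rate_hz * np.exp(-d2 / (2 * field_sigma_cm**2))
        events[c] = rng.random(n_frames) < rate / FPS
    scene = SessionScene(positions=pos, events=events, laps=laps, n_bins=n_bins,
                         speeds=np.full(n_frames, 10.0))
    scene.truth = {"centers_cm": centers, "n_fields": nf,
                   "peak_rate_hz": peak_rate_hz, "sigma_cm": field_sigma_cm}
    return scene
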
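"""Zero-inflated negative-binomial variational autoencoder for band matrices.

Each (pooled) band group of one chromosome is fitted independently.  For cell
``c`` with latent representation ``z_c ~ Normal(0, I_K)``, the count at locus
pair ``r`` is generated as

* rate ``lambda_r ~ Gamma`` with mean ``mu_r = eta_r(z_c, s_c)`` and shape
  ``delta_v`` shared by all pairs of band ``v`` — marginally the count
  ``N_r ~ Poisson(d_c * lambda_r)`` is negative binomial with mean
  ``d_c * mu_r`` and inverse-dispersion ``delta_v``;
* a Bernoulli dropout indicator ``T_r`` with probability
  ``pi_r = omega_r(z_c, s_c)`` forces the observed value to zero;
* the cell/band size factor ``d_c ~ LogNormal(mu_d, sigma_d^2)``, prior
  moments matched to the observed log group totals (per batch when the fit
  is batch-aware).

``eta`` outputs per-pair fractions through a softmax so they sum to one over
the group's locus pairs, making ``d_c`` identifiable as the group total
scale.  ``s_c`` is the (optional) batch label, one-hot encoded into both the
encoder input and the decoders.

Inference is amortized variational inference: an encoder network maps the
log1p-transformed counts to Gaussian posteriors over ``z`` and ``log d``, and
the evidence lower bound is maximized by Adam.  The implementation is plain
NumPy with hand-derived gradients (verified against finite differences in the
test suite); problems here are small enough that full-batch updates are both
fast and exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .contacts_io import BandMatrix, CellMetadata

logger = logging.getLogger("schicnd")

_EPS = 1e-8


# ---------------------------------------------------------------------------
# Pooling schedules


@dataclass
class PoolingSchedule:
    """Partition of bands 1..V into groups fitted by one model each."""

    strategy: int
    groups: list[list[int]]

    def __post_init__(self) -> None:
        flat = [v for g in self.groups for v in g]
        if sorted(flat) != list(range(1, len(flat) + 1)):
            raise ValueError("groups must partition bands 1..V")


def _chunk(start: int, V: int, sizes) -> list[list[int]]:
    groups, v = [], start
    for size in sizes:
        if v > V:
            break
        groups.append(list(range(v, min(v + size, V + 1))))
        v += size
    return groups


def pooling_schedule(V: int, strategy: int = 1,
                     max_groups: int | None = None) -> PoolingSchedule:
    """Build the band-pooling partition for ``V`` off-diagonal bands.

    Strategy 1 (default, progressive): group sizes grow 1, 2, 3, 4, ... —
    bands {1}, {2,3}, {4,5,6}, {7..10}, ...; with ``max_groups`` set, the
    final group absorbs all remaining bands once the cap is reached.
    Strategy 2: bands 1-10 individually, then sizes 2, 3, 4, ...
    Strategy 3: sizes 5, 10, 20, 40, ... (doubling).
    Strategy 4: every ten bands merged.
    Strategy 5: bands 1-10 individually, then every ten bands merged.
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    if strategy not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown pooling strategy {strategy}")

    def triangular():
        k = 1
        while True:
            yield k
            k += 1

    def doubling():
        k = 5
        while True:
            yield k
            k *= 2

    def tens():
        while True:
            yield 10

    def from_two():
        k = 2
        while True:
            yield k
            k += 1

    if strategy == 1:
        groups = _chunk(1, V, triangular())
        if max_groups is not None and len(groups) > max_groups:
            head = groups[: max_groups - 1]
            tail = [v for g in groups[max_groups - 1:] for v in g]
            groups = head + [tail]
    elif strategy == 2:
        singles = [[v] for v in range(1, min(10, V) + 1)]
        groups = singles + _chunk(11, V, from_two())
    elif strategy == 3:
        groups = _chunk(1, V, doubling())
    elif strategy == 4:
        groups = _chunk(1, V, tens())
    else:
        singles = [[v] for v in range(1, min(10, V) + 1)]
        groups = singles + _chunk(11, V, tens())
    return PoolingSchedule(strategy, groups)


def select_variable_bands(bands: list[BandMatrix],
                          keep_fraction: float = 1.0) -> list[BandMatrix]:
    """Keep the bands whose per-cell totals vary most across cells.

    Optional pre-filter (default keeps everything): bands are ranked by the
    across-cell variance of their band totals and the top fraction retained,
    in original band order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return list(bands)
    variances = [float(np.var(np.asarray(bm.matrix.sum(axis=1)).ravel()))
                 for bm in bands]
    n_keep = max(1, int(np.ceil(keep_fraction * len(bands))))
    order = np.argsort(variances)[::-1][:n_keep]
    keep = sorted(order)
    return [bands[i] for i in keep]


# ---------------------------------------------------------------------------
# Configuration and fit containers


@dataclass
class ScviConfig:
    """Hyper-parameters of the band-group model.

    The latent dimension defaults to 100, which suits full-scale data;
    reduced problems (and this package's test suite) use smaller K.
    """

    latent_dim: int = 100
    hidden_dim: int = 128
    epochs: int = 1000
    learning_rate: float = 3e-3
    seed: int = 0
    batch_aware: bool = False
    keep_fraction: float = 1.0  # optional variable-band pre-filter
    pool_strategy: int = 1
    max_groups: int | None = None


@dataclass
class BandModelFit:
    """Result of fitting one pooled band group."""

    group: list[int]
    chrom: str
    kept_cell_ids: list[str]
    filtered_cell_ids: list[str]
    latent: np.ndarray          # kept cells x K posterior means of z
    mean_fractions: np.ndarray  # kept cells x P, rows sum to 1
    dropout_probs: np.ndarray   # kept cells x P
    size_factors: np.ndarray    # kept cells, d_c = exp(E[log d])
    dispersions: dict[int, float]  # band v -> delta_v
    elbo_trace: np.ndarray      # per-epoch negative loss
    band_matrix: BandMatrix     # the (kept-cell) input, for de-noising
    batch_codes: np.ndarray


@dataclass
class LatentEmbedding:
    """Concatenated per-cell latent coordinates across groups/chromosomes."""

    cell_ids: list[str]
    matrix: np.ndarray
    provenance: list[tuple[str, tuple[int, ...]]]  # per column: (chrom, group)


# ---------------------------------------------------------------------------
# ZINB likelihood (also used directly by tests)


def zinb_logpmf(y: np.ndarray, mean: np.ndarray, theta: np.ndarray,
                pi: np.ndarray) -> np.ndarray:
    """Log pmf of the zero-inflated negative binomial.

    ``mean`` is the NB mean, ``theta`` the inverse-dispersion (Gamma shape;
    ``theta -> inf`` recovers Poisson), ``pi`` the dropout probability.
    """
    y = np.asarray(y, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), y.shape)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), y.shape)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), y.shape)
    log_theta_over = theta * (np.log(theta) - np.log(theta + mean))
    nb = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
          + log_theta_over + y * (np.log(mean + _EPS) - np.log(theta + mean)))
    with np.errstate(divide="ignore"):
        zero_case = np.logaddexp(np.log(pi + _EPS),
                                 np.log1p(-pi + _EPS) + log_theta_over)
        pos_case = np.log1p(-pi + _EPS) + nb
    return np.where(y == 0, zero_case, pos_case)


# ---------------------------------------------------------------------------
# The variational autoencoder


def _relu(x):
    return np.maximum(x, 0.0)


class ZinbVae:
    """Amortized VI for the per-band-group ZINB model (NumPy, full batch)."""

    def __init__(self, n_pairs: int, band_of_col: np.ndarray, n_batches: int,
                 cfg: ScviConfig, rng: np.random.Generator):
        self.P = n_pairs
        self.K = cfg.latent_dim
        self.H = cfg.hidden_dim
        self.B = max(1, n_batches)
        self.batch_aware = cfg.batch_aware and self.B > 1
        self.band_of_col = band_of_col
        self.bands = np.unique(band_of_col)
        self.band_slot = np.searchsorted(self.bands, band_of_col)
        self.rng = rng

        n_in = self.P + (self.B if self.batch_aware else 0)
        n_dec_in = self.K + (self.B if self.batch_aware else 0)

        def init(n_out, n_inp):
            return rng.normal(0.0, np.sqrt(2.0 / n_inp), size=(n_inp, n_out))

        H, K, P = self.H, self.K, self.P
        self.params = {
            "W1": init(H, n_in), "b1": np.zeros(H),
            "Wzm": init(K, H), "bzm": np.zeros(K),
            "Wzl": init(K, H), "bzl": np.zeros(K),
            "Wdm": init(1, H), "bdm": np.zeros(1),
            "Wdl": init(1, H), "bdl": np.zeros(1),
            "V1": init(H, n_dec_in), "c1": np.zeros(H),
            "Vo": init(P, H), "co": np.zeros(P),
            "Vg": init(P, H), "cg": np.zeros(P),
            "log_theta": np.zeros(len(self.bands)),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward pieces -----------------------------------------------------

    def _encode(self, x: np.ndarray, onehot: np.ndarray | None):
        p = self.params
        xin = np.hstack([x, onehot]) if self.batch_aware else x
        h_pre = xin @ p["W1"] + p["b1"]
        h = _relu(h_pre)
        z_mu = h @ p["Wzm"] + p["bzm"]
        z_lv = np.clip(h @ p["Wzl"] + p["bzl"], -15.0, 8.0)
        d_mu = (h @ p["Wdm"] + p["bdm"]).ravel()
        d_lv = np.clip((h @ p["Wdl"] + p["bdl"]).ravel(), -15.0, 8.0)
        return xin, h_pre, h, z_mu, z_lv, d_mu, d_lv

    def _decode(self, z: np.ndarray, onehot: np.ndarray | None):
        p = self.params
        u = np.hstack([z, onehot]) if self.batch_aware else z
        hd_pre = u @ p["V1"] + p["c1"]
        hd = _relu(hd_pre)
        o = hd @ p["Vo"] + p["co"]
        o = o - o.max(axis=1, keepdims=True)
        expo = np.exp(o)
        mu = expo / expo.sum(axis=1, keepdims=True)
        g = hd @ p["Vg"] + p["cg"]
        return u, hd_pre, hd, mu, g

    # -- training -----------------------------------------------------------

    def fit(self, y: np.ndarray, batch_codes: np.ndarray,
            prior_mu: np.ndarray, prior_var: np.ndarray,
            epochs: int, lr: float) -> np.ndarray:
        """Maximize the ELBO by full-batch Adam; returns the per-epoch ELBO."""
        x = np.log1p(y)
        onehot = None
        if self.batch_aware:
            onehot = np.eye(self.B)[batch_codes]
        trace = np.empty(epochs)
        for epoch in range(epochs):
            loss, grads = self._loss_and_grads(y, x, onehot, batch_codes,
                                               prior_mu, prior_var)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; inspect the input "
                    f"band group (P={self.P}, N={y.shape[0]})")
            self._adam_step(grads, lr)
            trace[epoch] = -loss
        return trace

    def _loss_and_grads(self, y, x, onehot, batch_codes, prior_mu, prior_var):
        p = self.params
        N = y.shape[0]
        xin, h_pre, h, z_mu, z_lv, d_mu, d_lv = self._encode(x, onehot)

        eps_z = self.rng.standard_normal(z_mu.shape)
        eps_d = self.rng.standard_normal(d_mu.shape)
        z = z_mu + eps_z * np.exp(z_lv / 2.0)
        logd = d_mu + eps_d * np.exp(d_lv / 2.0)
        d = np.exp(logd)

        u, hd_pre, hd, mu, g = self._decode(z, onehot)
        theta = np.exp(p["log_theta"])[self.band_slot]  # per column
        m = d[:, None] * mu

        # --- ZINB log-likelihood and its gradients w.r.t. m, g, theta
        log_ratio = np.log(theta) - np.log(theta + m)
        b_term = theta * log_ratio
        zero = y == 0
        sig_g = 1.0 / (1.0 + np.exp(-g))
        # y == 0:  ll = logaddexp(g, b) - softplus(g)
        s_gb = 1.0 / (1.0 + np.exp(-(g - b_term)))  # sigmoid(g - b)
        dll_dg = np.where(zero, s_gb - sig_g, -sig_g)
        dll_db = 1.0 - s_gb  # sigmoid(b - g), zero entries only
        dll_dm = np.where(
            zero,
            dll_db * (-theta / (theta + m)),
            y / (m + _EPS) - (y + theta) / (theta + m),
        )
        dll_dtheta = np.where(
            zero,
            dll_db * (log_ratio + 1.0 - theta / (theta + m)),
            digamma(y + theta) - digamma(theta) + log_ratio
            + 1.0 - (y + theta) / (theta + m),
        )
        ll_zero = np.logaddexp(g, b_term) - np.logaddexp(0.0, g)
        nb = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1) + b_term
              + y * (np.log(m + _EPS) - np.log(theta + m)))
        ll_pos = -np.logaddexp(0.0, g) + nb
        ll = np.where(zero, ll_zero, ll_pos).sum()

        kl_z = 0.5 * (z_mu ** 2 + np.exp(z_lv) - 1.0 - z_lv).sum()
        pm, pv = prior_mu[batch_codes], prior_var[batch_codes]
        kl_d = (0.5 * np.log(pv) - d_lv / 2.0
                + (np.exp(d_lv) + (d_mu - pm) ** 2) / (2.0 * pv) - 0.5).sum()
        loss = (-ll + kl_z + kl_d) / N

        # --- backward
        scale = -1.0 / N  # d(loss)/d(ll)
        dm = scale * dll_dm
        dg = scale * dll_dg
        dtheta_col = scale * dll_dtheta

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        # dispersion: log_theta per band slot
        dtheta_total = dtheta_col * theta  # chain through exp
        grads["log_theta"] = np.array([
            dtheta_total[:, self.band_slot == s].sum()
            for s in range(len(self.bands))
        ])

        # mean path: m = d * mu
        dmu = dm * d[:, None]
        dlogd_lik = (dm * m).sum(axis=1)
        # softmax backprop
        do = mu * (dmu - (mu * dmu).sum(axis=1, keepdims=True))

        grads["Vo"] = hd.T @ do
        grads["co"] = do.sum(axis=0)
        grads["Vg"] = hd.T @ dg
        grads["cg"] = dg.sum(axis=0)
        dhd = do @ p["Vo"].T + dg @ p["Vg"].T
        dhd_pre = dhd * (hd_pre > 0)
        grads["V1"] = u.T @ dhd_pre
        grads["c1"] = dhd_pre.sum(axis=0)
        du = dhd_pre @ p["V1"].T
        dz = du[:, : self.K]

        # KL(z) and reparameterization
        dz_mu = dz + z_mu / N
        dz_lv = dz * (z - z_mu) / 2.0 + 0.5 * (np.exp(z_lv) - 1.0) / N
        # KL(d) and reparameterization
        dd_mu = dlogd_lik + (d_mu - pm) / pv / N
        dd_lv = (dlogd_lik * (logd - d_mu) / 2.0
                 + (-0.5 + np.exp(d_lv) / (2.0 * pv)) / N)
        # clip pass-through: zero gradient where the clip was active
        dz_lv *= (z_lv > -15.0) & (z_lv < 8.0)
        dd_lv *= (d_lv > -15.0) & (d_lv < 8.0)

        grads["Wzm"] = h.T @ dz_mu
        grads["bzm"] = dz_mu.sum(axis=0)
        grads["Wzl"] = h.T @ dz_lv
        grads["bzl"] = dz_lv.sum(axis=0)
        grads["Wdm"] = h.T @ dd_mu[:, None]
        grads["bdm"] = np.array([dd_mu.sum()])
        grads["Wdl"] = h.T @ dd_lv[:, None]
        grads["bdl"] = np.array([dd_lv.sum()])

        dh = (dz_mu @ p["Wzm"].T + dz_lv @ p["Wzl"].T
              + dd_mu[:, None] @ p["Wdm"].T + dd_lv[:, None] @ p["Wdl"].T)
        dh_pre = dh * (h_pre > 0)
        grads["W1"] = xin.T @ dh_pre
        grads["b1"] = dh_pre.sum(axis=0)
        return loss, grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- deterministic outputs ----------------------------------------------

    def transform(self, y: np.ndarray, batch_codes: np.ndarray):
        """Posterior means of z and log d, and decoder outputs at E[z]."""
        x = np.log1p(y)
        onehot = np.eye(self.B)[batch_codes] if self.batch_aware else None
        _, _, _, z_mu, _, d_mu, _ = self._encode(x, onehot)
        _, _, _, mu, g = self._decode(z_mu, onehot)
        pi = 1.0 / (1.0 + np.exp(-g))
        return z_mu, d_mu, mu, pi


# ---------------------------------------------------------------------------
# Fitting driver


def fit_band_group(bm: BandMatrix, meta: CellMetadata | None,
                   cfg: ScviConfig) -> BandModelFit | None:
    """Fit the ZINB model to one pooled band group.

    Cells with no interaction across all of the group's locus pairs are
    removed before inference; their ids are recorded so their embeddings can
    be zero-imputed downstream.  Returns ``None`` (with a log record) when
    fewer than two cells remain.
    """
    y_full = np.asarray(bm.matrix.todense(), dtype=float)
    totals = y_full.sum(axis=1)
    keep = totals > 0
    kept_ids = [c for c, k in zip(bm.cell_ids, keep) if k]
    filtered_ids = [c for c, k in zip(bm.cell_ids, keep) if not k]
    if keep.sum() < 2:
        logger.warning("band group %s on %s: <2 cells with signal, skipped",
                       bm.bands, bm.chrom)
        return None
    y = y_full[keep]

    if meta is not None and cfg.batch_aware:
        batch_codes = meta.batches_for(kept_ids)
    else:
        batch_codes = np.zeros(len(kept_ids), dtype=int)
    n_batches = int(batch_codes.max()) + 1

    # LogNormal prior moments for d, matched to observed log group totals
    log_tot = np.log(y.sum(axis=1))
    prior_mu = np.empty(n_batches)
    prior_var = np.empty(n_batches)
    for b in range(n_batches):
        vals = log_tot[batch_codes == b]
        prior_mu[b] = vals.mean() if vals.size else log_tot.mean()
        prior_var[b] = max(float(np.var(vals)), 1e-4) if vals.size > 1 else 1.0

    rng = np.random.default_rng(cfg.seed)
    vae = ZinbVae(y.shape[1], bm.band_of_column, n_batches, cfg, rng)
    trace = vae.fit(y, batch_codes, prior_mu, prior_var,
                    cfg.epochs, cfg.learning_rate)
    z_mu, d_mu, mu, pi = vae.transform(y, batch_codes)
    theta = np.exp(vae.params["log_theta"])
    kept_bm = BandMatrix(bm.chrom, list(bm.bands), kept_ids,
                         bm.matrix[np.flatnonzero(keep)], bm.D)
    return BandModelFit(
        group=list(bm.bands), chrom=bm.chrom, kept_cell_ids=kept_ids,
        filtered_cell_ids=filtered_ids, latent=z_mu,
        mean_fractions=mu, dropout_probs=pi, size_factors=np.exp(d_mu),
        dispersions={int(v): float(t) for v, t in zip(vae.bands, theta)},
        elbo_trace=trace, band_matrix=kept_bm, batch_codes=batch_codes,
    )


def assemble_latent(fits: list[BandModelFit],
                    all_cells: list[str]) -> LatentEmbedding:
    """Concatenate per-group latent means over (chrom, group) columns.

    Cells filtered out of a group get exact zeros in that group's columns.
    """
    if len(set(all_cells)) != len(all_cells):
        raise ValueError("duplicate cell ids")
    row_of = {c: i for i, c in enumerate(all_cells)}
    fits = sorted(fits, key=lambda f: (f.chrom, tuple(f.group)))
    blocks, provenance = [], []
    for fit in fits:
        k = fit.latent.shape[1]
        block = np.zeros((len(all_cells), k))
        for c, row in zip(fit.kept_cell_ids, fit.latent):
            block[row_of[c]] = row
        blocks.append(block)
        provenance.extend([(fit.chrom, tuple(fit.group))] * k)
    matrix = np.hstack(blocks) if blocks else np.zeros((len(all_cells), 0))
    return LatentEmbedding(list(all_cells), matrix, provenance)


def denoise_band_group(fit: BandModelFit) -> BandMatrix:
    """Expected dropout-free NB mean ``d_c * mu_r`` per kept cell and pair."""
    values = fit.size_factors[:, None] * fit.mean_fractions
    from scipy import sparse
    mat = sparse.csr_matrix(values)
    bm = fit.band_matrix
    return BandMatrix(bm.chrom, list(bm.bands), list(fit.kept_cell_ids),
                      mat, bm.D)


def run_scvi3d(table, meta: CellMetadata | None, cfg: ScviConfig,
               chroms: list[str] | None = None):
    """Band-split every chromosome, fit each pooled group, assemble embeddings.

    Returns ``(embedding, fits)``.
    """
    from .contacts_io import band_split, pool_bands

    chroms = chroms or sorted(table.chrom_sizes)
    all_cells = table.cell_ids
    fits: list[BandModelFit] = []
    for chrom in chroms:
        bands = band_split(table, chrom, drop_diagonal=True,
                           cell_ids=all_cells)
        bands = select_variable_bands(bands, cfg.keep_fraction)
        available = sorted(bm.bands[0] for bm in bands)
        schedule = pooling_schedule(max(available), cfg.pool_strategy,
                                    cfg.max_groups)
        for group in schedule.groups:
            members = [v for v in group if v in available]
            if not members:
                continue
            pooled = pool_bands(bands, members)
            fit = fit_band_group(pooled, meta, cfg)
            if fit is not None:
                fits.append(fit)
    return assemble_latent(fits, all_cells), fits
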
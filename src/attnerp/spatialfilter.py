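"""Max-SNR spatial filtering of ear-EEG via generalized eigendecomposition.

The filter seeks the weight vector ``w`` (one weight per ear channel) that
maximizes the energy of the filtered *average target epoch* relative to the
average energy of filtered *non-target epochs*:

    maximize  w' R_T w   subject to   w' R_N w = 1,

where ``R_T = X_T X_T'`` is the autocorrelation of the averaged target
epoch ``X_T`` and ``R_N = X_N X_N'`` that of the non-target epochs
concatenated along time.  The solution is the top generalized eigenvector
of ``(R_T, R_N)``; the maximized ratio equals the top generalized
eigenvalue.  Any positive rescaling of a maximizer keeps the Rayleigh
quotient, so the unit-output-power constraint pins the scale.

Because within-ear average referencing makes ``R_N`` rank deficient (rank
<= C-1), it is shrunk toward a scaled identity before inversion.

Usage follows the model/results idiom::

    model = MaxSNRFilter(target_epochs, nontarget_epochs, ear="left")
    res = model.fit()
    virtual = res.apply(heldout_epochs)   # single-channel EpochSet
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .core import EpochSet, ERPWave, ValidationError, concatenate_epochs
from . import erp as _erp


def compute_covariances(
    target_epochs: EpochSet | np.ndarray,
    nontarget_epochs: EpochSet | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(R_T, R_N) from target and non-target epochs.

    ``R_T`` is built from the *average* target epoch (epochs x channels x
    samples -> channels x samples mean), ``R_N`` from the non-target
    epochs concatenated along the time axis (equivalently, the sum of the
    per-epoch outer products).  Both are C x C, symmetric and PSD.
    """
    Xt = target_epochs.data if isinstance(target_epochs, EpochSet) else np.asarray(target_epochs, float)
    Xn = nontarget_epochs.data if isinstance(nontarget_epochs, EpochSet) else np.asarray(nontarget_epochs, float)
    if Xt.ndim == 2:
        Xt = Xt[None]
    if Xn.ndim == 2:
        Xn = Xn[None]
    if Xt.shape[0] == 0 or Xn.shape[0] == 0:
        raise ValidationError("need at least one epoch in each condition")
    if Xt.shape[1:] != Xn.shape[1:]:
        raise ValidationError(
            f"epoch dimensions differ: {Xt.shape[1:]} vs {Xn.shape[1:]}"
        )
    XT = Xt.mean(axis=0)                      # C x N average target epoch
    R_T = XT @ XT.T
    C = Xn.shape[1]
    XN = np.concatenate(list(Xn), axis=1)     # C x (N * n_N)
    R_N = XN @ XN.T
    R_T = 0.5 * (R_T + R_T.T)
    R_N = 0.5 * (R_N + R_N.T)
    return R_T, R_N


def _regularize(R_N: np.ndarray, shrinkage: float) -> np.ndarray:
    """Shrink toward a scaled identity: (1-g) R_N + g (tr R_N / C) I."""
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    C = R_N.shape[0]
    return (1.0 - shrinkage) * R_N + shrinkage * (np.trace(R_N) / C) * np.eye(C)


@dataclass
class MaxSNRFilterResult:
    """Fitted max-SNR spatial filter.

    ``w`` satisfies ``w' R_N w = 1`` (with respect to the *unregularized*
    ``R_N`` whenever it is non-degenerate along ``w``); ``eigenvalue`` is
    the achieved objective ``w' R_T w``.
    """

    w: np.ndarray
    eigenvalue: float
    R_T: np.ndarray
    R_N: np.ndarray
    shrinkage: float
    channel_labels: list[str] | None = None
    trained_on: tuple[str, ...] = ()
    ear: str | None = None
    degenerate_target: bool = False

    # -- diagnostics -------------------------------------------------------
    def constraint_residual(self) -> float:
        """|w' R_N w - 1| (unit non-target output power, the fit constraint)."""
        return float(abs(self.w @ self.R_N @ self.w - 1.0))

    def stationarity_residual(self) -> float:
        """Relative residual of R_T w = lambda R_N_reg w at the solution."""
        Rn = _regularize(self.R_N, self.shrinkage)
        r = self.R_T @ self.w - self.eigenvalue * (Rn @ self.w)
        denom = np.linalg.norm(self.R_T @ self.w) + 1e-300
        return float(np.linalg.norm(r) / denom)

    # -- application -------------------------------------------------------
    def apply(self, epochs: EpochSet) -> EpochSet:
        """Map each epoch X_i (C x N) to the virtual channel w' X_i (1 x N)."""
        if self.channel_labels is not None:
            if list(epochs.channel_labels) != list(self.channel_labels):
                raise ValidationError(
                    "epoch channels do not match the filter's training channels"
                )
        elif epochs.n_channels != self.w.size:
            raise ValidationError("channel count mismatch")
        virtual = np.einsum("c,ecs->es", self.w, epochs.data)[:, None, :]
        label = f"maxsnr_{self.ear or 'filter'}"
        return EpochSet(
            virtual,
            epochs.times_ms,
            epochs.sampling_rate,
            [label],
            {label: epochs.channel_groups.get(epochs.channel_labels[0], "scalp")},
            epochs.conditions,
            {},
            epochs.events,
        )

    def summary(self) -> str:
        lines = [
            "Max-SNR spatial filter (generalized eigenvalue problem)",
            "=" * 55,
            f"channels:          {self.w.size}"
            + (f" ({', '.join(self.channel_labels)})" if self.channel_labels else ""),
            f"ear:               {self.ear or '-'}",
            f"trained on:        {', '.join(self.trained_on) or '-'}",
            f"shrinkage gamma:   {self.shrinkage:g}",
            f"top eigenvalue:    {self.eigenvalue:.6g}",
            f"constraint |w'R_N w - 1|: {self.constraint_residual():.3g}",
            f"degenerate target: {self.degenerate_target}",
            "weights:",
        ]
        for i, wi in enumerate(self.w):
            name = self.channel_labels[i] if self.channel_labels else f"ch{i}"
            lines.append(f"  {name:>8s}  {wi:+.6f}")
        return "\n".join(lines)


class MaxSNRFilter:
    """Model object: builds (R_T, R_N) from epochs and fits the filter.

    Parameters
    ----------
    target_epochs, nontarget_epochs
        EpochSets (or raw epochs x channels x samples arrays) of the two
        conditions, on the same channel set.
    shrinkage
        Fraction of identity shrinkage applied to R_N before solving;
        needed because within-ear average referencing makes R_N rank
        deficient.
    ear
        Optional tag ("left"/"right") recorded in the result.
    trained_on
        Provenance tags (e.g. paradigm names) recorded in the result.
    """

    def __init__(
        self,
        target_epochs: EpochSet | np.ndarray,
        nontarget_epochs: EpochSet | np.ndarray,
        shrinkage: float = 0.05,
        ear: str | None = None,
        trained_on: Sequence[str] = (),
    ):
        self.R_T, self.R_N = compute_covariances(target_epochs, nontarget_epochs)
        self.shrinkage = shrinkage
        self.ear = ear
        self.trained_on = tuple(trained_on)
        if isinstance(target_epochs, EpochSet):
            self.channel_labels = list(target_epochs.channel_labels)
            self._XT = target_epochs.data.mean(axis=0)
            self._times_ms = target_epochs.times_ms
        else:
            self.channel_labels = None
            self._XT = np.asarray(target_epochs, float)
            if self._XT.ndim == 3:
                self._XT = self._XT.mean(axis=0)
            self._times_ms = None

    @classmethod
    def from_covariances(
        cls,
        R_T: np.ndarray,
        R_N: np.ndarray,
        shrinkage: float = 0.05,
        ear: str | None = None,
        trained_on: Sequence[str] = (),
    ) -> "MaxSNRFilter":
        obj = cls.__new__(cls)
        R_T = np.asarray(R_T, float)
        R_N = np.asarray(R_N, float)
        if R_T.shape != R_N.shape or R_T.ndim != 2 or R_T.shape[0] != R_T.shape[1]:
            raise ValidationError("R_T and R_N must be square and same shape")
        obj.R_T = 0.5 * (R_T + R_T.T)
        obj.R_N = 0.5 * (R_N + R_N.T)
        obj.shrinkage = shrinkage
        obj.ear = ear
        obj.trained_on = tuple(trained_on)
        obj.channel_labels = None
        obj._XT = None
        obj._times_ms = None
        return obj

    def fit(self) -> MaxSNRFilterResult:
        """Solve the GEVD and return the top-eigenvector filter.

        The eigenvector of the largest generalized eigenvalue of
        ``(R_T, R_N_reg)`` is rescaled to satisfy ``w' R_N w = 1`` and its
        sign is chosen so the filtered average-target waveform has a
        non-negative mean over 400-800 ms (positive-going component, like
        the scalp P3b); lacking training epochs, the largest-magnitude
        weight is made positive.
        """
        Rn = _regularize(self.R_N, self.shrinkage)
        C = Rn.shape[0]
        # degenerate target: objective ill-defined, fall back with warning
        degenerate = bool(
            np.trace(self.R_T) <= 1e-12 * max(np.trace(self.R_N), 1.0)
        )
        try:
            if degenerate:
                warnings.warn(
                    "average target epoch is (near) zero; returning the "
                    "direction of largest non-target variance instead",
                    RuntimeWarning,
                )
                vals, vecs = linalg.eigh(Rn)
                w = vecs[:, -1]
            else:
                vals, vecs = linalg.eigh(self.R_T, Rn)
                w = vecs[:, -1]
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "generalized eigendecomposition failed; R_N is numerically "
                "singular -- increase the shrinkage"
            ) from exc

        # normalise against the raw R_N when possible (Eq. constraint),
        # falling back to the regularized matrix if w lies in its null space
        q = float(w @ self.R_N @ w)
        if q > 1e-12 * float(w @ Rn @ w):
            w = w / np.sqrt(q)
        else:
            w = w / np.sqrt(float(w @ Rn @ w))

        # sign convention
        flip = 1.0
        if self._XT is not None and self._times_ms is not None:
            filt = w @ self._XT
            mask = (self._times_ms >= 400.0) & (self._times_ms <= 800.0)
            if mask.any() and filt[mask].mean() < 0:
                flip = -1.0
        elif self._XT is not None:
            if (w @ self._XT).mean() < 0:
                flip = -1.0
        else:
            if w[np.argmax(np.abs(w))] < 0:
                flip = -1.0
        w = flip * w

        return MaxSNRFilterResult(
            w=w,
            eigenvalue=float(w @ self.R_T @ w) if not degenerate else 0.0,
            R_T=self.R_T,
            R_N=self.R_N,
            shrinkage=self.shrinkage,
            channel_labels=self.channel_labels,
            trained_on=self.trained_on,
            ear=self.ear,
            degenerate_target=degenerate,
        )


def solve_filter(
    R_T: np.ndarray, R_N: np.ndarray, shrinkage: float = 0.05
) -> MaxSNRFilterResult:
    """Functional wrapper: fit the filter directly from covariances."""
    return MaxSNRFilter.from_covariances(R_T, R_N, shrinkage=shrinkage).fit()


def apply_filter(epochs: EpochSet, model: MaxSNRFilterResult) -> EpochSet:
    """Functional wrapper around :meth:`MaxSNRFilterResult.apply`."""
    return model.apply(epochs)


@dataclass
class CrossTaskOutput:
    """Held-out filtering results for one paradigm."""

    filter: MaxSNRFilterResult
    target_erp: ERPWave
    nontarget_erp: ERPWave
    filtered_target: EpochSet
    filtered_nontarget: EpochSet


def cross_task_validate(
    data: Mapping[str, tuple[EpochSet, EpochSet]],
    ear: str | None = None,
    shrinkage: float = 0.05,
) -> dict[str, CrossTaskOutput]:
    """Leave-one-paradigm-out filtering.

    For each paradigm ``p`` a filter is trained on the pooled target and
    non-target epochs of *all other* paradigms and applied to ``p``'s
    epochs, so the evaluated paradigm never contributes to its own filter.
    Returns per-paradigm filtered epochs and their average ERPs.
    """
    paradigms = list(data)
    if len(paradigms) < 2:
        raise ValidationError(
            "cross-task validation needs at least two paradigms"
        )
    out: dict[str, CrossTaskOutput] = {}
    for p in paradigms:
        others = [q for q in paradigms if q != p]
        train_t = concatenate_epochs([data[q][0] for q in others])
        train_n = concatenate_epochs([data[q][1] for q in others])
        res = MaxSNRFilter(
            train_t, train_n, shrinkage=shrinkage, ear=ear,
            trained_on=sorted(others),
        ).fit()
        f_t = res.apply(data[p][0])
        f_n = res.apply(data[p][1])
        ch = f_t.channel_labels[0]
        t_erp = ERPWave(f_t.data.mean(axis=0), f_t.times_ms, "target",
                        f_t.n_epochs, [ch])
        n_erp = ERPWave(f_n.data.mean(axis=0), f_n.times_ms, "nontarget",
                        f_n.n_epochs, [ch])
        out[p] = CrossTaskOutput(res, t_erp, n_erp, f_t, f_n)
    return out
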
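"""Ensemble contact dynamics: mean and Max-Min residue-pair matrices.

For a multi-model structure (NMR ensemble, MD snapshots) every model
yields a residue-pair contact table; stacking them gives, per pair, the
mean contact measure and its range (max - min) across models.  A pair
absent from a model contributes 0 for that model -- intermittent contacts
therefore show a large range, which is exactly the flexibility signal of
interest.  Pairs whose mean is moderate but whose range is wide (defaults:
mean >= 30 A^3, range >= 100 A^3) are flagged as "flexible contacts".
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "EnsembleMatrices",
    "ensemble_matrices",
    "flag_flexible_contacts",
    "render_heatmap",
    "render_atom_scatter",
    "DEFAULT_MIN_MEAN",
    "DEFAULT_MIN_RANGE",
]

DEFAULT_MIN_MEAN = 30.0    # A^3
DEFAULT_MIN_RANGE = 100.0  # A^3

_METRIC_ATTR = {"area": "Sr", "volume": "Vr", "aowv": "AOWVr"}


@dataclass
class EnsembleMatrices:
    """Symmetric mean and range matrices over an ensemble of models."""

    residues: list[str]           # axis labels, canonical order
    mean: np.ndarray              # (n, n)
    range: np.ndarray             # (n, n), elementwise max - min
    n_models: int

    def pair_value(self, res_a: str, res_b: str) -> tuple[float, float]:
        i, j = self.residues.index(res_a), self.residues.index(res_b)
        return float(self.mean[i, j]), float(self.range[i, j])

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (pd.DataFrame(self.mean, index=self.residues, columns=self.residues),
                pd.DataFrame(self.range, index=self.residues, columns=self.residues))


def _pair_key(summary) -> tuple[str, str]:
    from .aggregate import residue_label
    return (residue_label(summary.name_a, summary.residue_a),
            residue_label(summary.name_b, summary.residue_b))


def ensemble_matrices(per_model_pairs, metric: str = "volume") -> EnsembleMatrices:
    """Mean/range matrices from per-model residue-pair summary lists.

    *per_model_pairs*: one list of :class:`ResiduePairSummary` per model.
    *metric*: ``area`` (Sr), ``volume`` (Vr), ``aowv`` (AOWVr) or
    ``frequency`` (presence/absence per model).
    """
    if not per_model_pairs:
        raise ValueError("need at least one model")
    frequency = metric == "frequency"
    if not frequency and metric not in _METRIC_ATTR:
        raise ValueError(f"unknown metric {metric!r}")

    residues: list[str] = []
    seen = set()
    values: list[dict[tuple[str, str], float]] = []
    for pairs in per_model_pairs:
        model_vals: dict[tuple[str, str], float] = {}
        for p in pairs:
            key = _pair_key(p)
            for r in key:
                if r not in seen:
                    seen.add(r)
                    residues.append(r)
            if frequency:
                v = 1.0
            else:
                v = getattr(p, _METRIC_ATTR[metric])
                if v is None:
                    raise ValueError(
                        f"metric {metric!r} was not computed for pair {key}")
            model_vals[key] = model_vals.get(key, 0.0) + float(v)
        values.append(model_vals)

    residues = sorted(residues)
    n = len(residues)
    idx = {r: i for i, r in enumerate(residues)}
    n_models = len(per_model_pairs)
    stack = np.zeros((n_models, n, n))
    for m, model_vals in enumerate(values):
        for (ra, rb), v in model_vals.items():
            i, j = idx[ra], idx[rb]
            stack[m, i, j] += v
            if i != j:
                stack[m, j, i] += v
    mean = stack.mean(axis=0)
    rng = stack.max(axis=0) - stack.min(axis=0)
    return EnsembleMatrices(residues=residues, mean=mean, range=rng,
                            n_models=n_models)


def flag_flexible_contacts(m: EnsembleMatrices,
                           min_mean: float = DEFAULT_MIN_MEAN,
                           min_range: float = DEFAULT_MIN_RANGE):
    """Residue pairs with mean >= min_mean and range >= min_range.

    Returns ``[(res_a, res_b, mean, range), ...]`` sorted by descending
    range (ties broken by residue labels, so the order is deterministic).
    """
    if min_mean < 0 or min_range < 0:
        raise ValueError("thresholds must be non-negative")
    out = []
    n = len(m.residues)
    for i in range(n):
        for j in range(i + 1, n):
            mu, rg = float(m.mean[i, j]), float(m.range[i, j])
            if (mu >= min_mean and rg >= min_range
                    and (mu > 0.0 or rg > 0.0)):
                out.append((m.residues[i], m.residues[j], mu, rg))
    out.sort(key=lambda t: (-t[3], t[0], t[1]))
    return out


def render_heatmap(m: EnsembleMatrices, path, highlight=(),
                   which: str = "mean", title: str | None = None):
    """Write a residue-pair heatmap; highlighted pairs get red markers."""
    if not m.residues:
        raise ValueError("empty matrix")
    mat = m.mean if which == "mean" else m.range
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="viridis", origin="lower", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="contact measure")
    idx = {r: i for i, r in enumerate(m.residues)}
    for pair in highlight:
        ra, rb = pair[0], pair[1]
        i, j = idx[ra], idx[rb]
        ax.plot([j, i], [i, j], "r.", markersize=8)
    step = max(1, len(m.residues) // 20)
    ticks = range(0, len(m.residues), step)
    ax.set_xticks(list(ticks))
    ax.set_xticklabels([m.residues[t] for t in ticks], rotation=90, fontsize=6)
    ax.set_yticks(list(ticks))
    ax.set_yticklabels([m.residues[t] for t in ticks], fontsize=6)
    ax.set_title(title or f"{which} contact matrix ({m.n_models} models)")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "contactgrid"})
    plt.close(fig)
    return path


def render_atom_scatter(atoms, path, title: str | None = None):
    """3D scatter of solute heavy-atom positions for one model."""
    atoms = [a for a in atoms if not getattr(a, "is_water", False)]
    if not atoms:
        raise ValueError("no solute atoms to plot")
    xyz = np.array([a.position for a in atoms], float)
    colors = ["tab:blue" if a.element == "C"
              else "tab:red" if a.element == "O"
              else "tab:cyan" if a.element == "N"
              else "tab:orange" for a in atoms]
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(xyz[:, 0], xyz[:, 1], xyz[:, 2], c=colors, s=12)
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    ax.set_zlabel("z (A)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "contactgrid"})
    plt.close(fig)
    return path
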
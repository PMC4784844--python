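"""Stimulus batteries and the derived filling-in quantities.

Runs bar batteries on intact and lesioned networks, records steady-state
responses in a long-format table, and computes normalized response
profiles, the supra-additivity (AND-gate) test, shifting-bar curves,
perceptual-image similarity and the misalignment completion curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blind_spot import BlindSpotMask
from .model_core import HPCNetwork, perceptual_image, relax_to_steady_state
from .preprocessing import remove_dc, whiten
from .synthetic_data import BarSpec, Stimulus, make_bar_pair

__all__ = [
    "ResponseTable",
    "CompletionCurve",
    "run_stimulus_battery",
    "normalize_responses",
    "top_k_neurons",
    "nonlinearity_test",
    "shifting_bar_profile",
    "completion_index",
    "misalignment_curve",
    "percept_similarity",
    "percept_correlation",
]


@dataclass
class ResponseTable:
    """Long-format steady-state responses plus per-run percepts.

    ``df`` columns: network, stimulus, level, module, neuron, response
    (module is -1 at level 2) and, after :func:`normalize_responses`,
    ``normalized``. ``percepts``/``energies``/``converged`` are keyed by
    (network, stimulus label).
    """

    df: pd.DataFrame
    percepts: dict
    energies: dict
    converged: dict
    unnormalized_scopes: list | None = None


@dataclass(frozen=True)
class CompletionCurve:
    """Completion index per vertical offset of the right bar segment."""

    offsets: tuple
    index: tuple


def run_stimulus_battery(
    networks,
    stimuli,
    whiten_filter=None,
    step: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 4000,
) -> ResponseTable:
    """Run every stimulus through every network to steady state.

    ``networks`` is a mapping network_id -> HPCNetwork. Stimuli are
    DC-removed (and optionally whitened) before inference; states start at
    zero. Non-converged runs are flagged, not dropped.
    """
    labels = [s.label for s in stimuli]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate stimulus labels in battery")
    rows = []
    percepts, energies, converged = {}, {}, {}
    for net_id, net in networks.items():
        for stim in stimuli:
            x = remove_dc(stim.pixels)
            if whiten_filter is not None:
                x = whiten(x, whiten_filter)
            res = relax_to_steady_state(x, net, step=step, tol=tol, max_iter=max_iter)
            key = (net_id, stim.label)
            percepts[key] = perceptual_image(net, res)
            energies[key] = float(res.E_trace[-1])
            converged[key] = bool(res.converged)
            for m in range(net.geometry.n_modules):
                for i in range(net.n1):
                    rows.append((net_id, stim.label, 1, m, i, res.r1[m, i]))
            if res.r2 is not None:
                for i in range(net.n2):
                    rows.append((net_id, stim.label, 2, -1, i, res.r2[i]))
    df = pd.DataFrame(
        rows, columns=["network", "stimulus", "level", "module", "neuron", "response"]
    )
    return ResponseTable(df=df, percepts=percepts, energies=energies, converged=converged)


def normalize_responses(table: ResponseTable) -> ResponseTable:
    """Divide responses by the max |response| within each (network, level).

    All-zero scopes are left unnormalized and flagged.
    """
    if table.df.empty:
        raise ValueError("response table is empty")
    df = table.df.copy()
    df["normalized"] = np.nan
    flagged = []
    for (net, level), idx in df.groupby(["network", "level"]).groups.items():
        vals = df.loc[idx, "response"]
        peak = vals.abs().max()
        if peak == 0:
            flagged.append((net, level))
            df.loc[idx, "normalized"] = vals
        else:
            df.loc[idx, "normalized"] = vals / peak
    return ResponseTable(
        df=df,
        percepts=table.percepts,
        energies=table.energies,
        converged=table.converged,
        unnormalized_scopes=flagged,
    )


def _module_slice(df: pd.DataFrame, network, module, level=1) -> pd.DataFrame:
    sel = (df["network"] == network) & (df["level"] == level)
    if level == 1:
        sel &= df["module"] == module
    return df[sel]


def top_k_neurons(table: ResponseTable, network, module: int, k: int, level: int = 1):
    """Indices of the k most responsive neurons (max |response| over the
    battery), ties broken by lower index."""
    col = "normalized" if "normalized" in table.df.columns else "response"
    sub = _module_slice(table.df, network, module, level)
    if sub.empty:
        raise ValueError("no rows for the requested network/module")
    peak = sub.groupby("neuron")[col].apply(lambda s: s.abs().max())
    if k > len(peak):
        raise ValueError("k exceeds the neuron count")
    order = sorted(peak.index, key=lambda i: (-peak[i], i))
    return list(order[:k])


def nonlinearity_test(
    table: ResponseTable, network, k: int = 8, module: int | None = None
) -> dict:
    """AND-gate test: is the response to ab larger than the sum a + b?

    Means are of |normalized response| over the k most responsive neurons
    of the blind-spot module. The c (inside-blind-spot) condition is
    reported but does not enter the pass criterion.
    """
    if "normalized" not in table.df.columns:
        table = normalize_responses(table)
    df = table.df
    present = set(df[df["network"] == network]["stimulus"])
    missing = {"a", "b", "c", "ab"} - present
    if missing:
        raise ValueError(f"battery missing conditions: {sorted(missing)}")
    if module is None:
        module = _central_module(df, network)
    neurons = top_k_neurons(table, network, module, k)
    sub = _module_slice(df, network, module)
    sub = sub[sub["neuron"].isin(neurons)]
    means = {
        lab: float(sub[sub["stimulus"] == lab]["normalized"].abs().mean())
        for lab in ("a", "b", "c", "ab")
    }
    mean_a_plus_b = means["a"] + means["b"]
    return {
        "mean_a": means["a"],
        "mean_b": means["b"],
        "mean_c": means["c"],
        "mean_ab": means["ab"],
        "mean_a_plus_b": mean_a_plus_b,
        "passes": bool(means["ab"] > mean_a_plus_b),
        "neurons": neurons,
        "module": module,
    }


def _central_module(df: pd.DataFrame, network) -> int:
    n_modules = int(df[(df["network"] == network) & (df["level"] == 1)]["module"].max()) + 1
    return n_modules // 2


def shifting_bar_profile(
    table: ResponseTable, network, neurons, module: int | None = None
) -> pd.DataFrame:
    """|normalized response| per neuron versus bar end position.

    Expects stimulus labels of the form ``shift_NN``; returns a frame
    indexed by end column with one column per neuron.
    """
    if "normalized" not in table.df.columns:
        table = normalize_responses(table)
    df = table.df
    if module is None:
        module = _central_module(df, network)
    sub = _module_slice(df, network, module)
    sub = sub[sub["stimulus"].str.startswith("shift_") & sub["neuron"].isin(neurons)]
    sub = sub.assign(end_col=sub["stimulus"].str.removeprefix("shift_").astype(int))
    prof = sub.pivot_table(
        index="end_col", columns="neuron", values="normalized", aggfunc="first"
    ).abs()
    return prof.sort_index()


def completion_index(
    image: np.ndarray, bar: BarSpec, mask: BlindSpotMask
) -> float:
    """Correlation, over blind-spot pixels, with the completed-bar template.

    The template is the aligned bar drawn straight through the blind spot
    at the bar's row. Returns 0 if either side is constant over the
    blind-spot pixels.
    """
    image = np.asarray(image, dtype=float)
    template = np.zeros_like(mask.indicator)
    template[bar.row : bar.row + bar.thickness, :] = bar.amplitude
    hole = mask.indicator == 0
    a = image[hole]
    b = template[hole]
    if a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def misalignment_curve(
    network: HPCNetwork,
    mask: BlindSpotMask,
    spec: BarSpec | None = None,
    offsets=range(-3, 4),
    **relax_opts,
) -> CompletionCurve:
    """Completion index of the lesioned network's percept per offset."""
    spec = spec or BarSpec()
    offsets = tuple(int(o) for o in offsets)
    stimuli = [make_bar_pair(spec, o) for o in offsets]
    table = run_stimulus_battery({"bs": network}, stimuli, **relax_opts)
    idx = tuple(
        completion_index(table.percepts[("bs", s.label)], spec, mask) for s in stimuli
    )
    return CompletionCurve(offsets=offsets, index=idx)


def percept_correlation(table: ResponseTable, key_a, key_b) -> float:
    """Pearson correlation between two recorded percepts (0 if degenerate)."""
    a = table.percepts[key_a].ravel()
    b = table.percepts[key_b].ravel()
    if a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def percept_similarity(table: ResponseTable, network_pair) -> pd.DataFrame:
    """Per-stimulus percept correlation between two networks.

    Degenerate (constant) percepts report correlation 0 with a flag.
    """
    net_a, net_b = network_pair
    labels = sorted({lab for (n, lab) in table.percepts if n == net_a})
    rows = []
    for lab in labels:
        if (net_b, lab) not in table.percepts:
            continue
        a = table.percepts[(net_a, lab)].ravel()
        b = table.percepts[(net_b, lab)].ravel()
        degenerate = a.std() < 1e-12 or b.std() < 1e-12
        corr = 0.0 if degenerate else float(np.corrcoef(a, b)[0, 1])
        rows.append({"stimulus": lab, "correlation": corr, "degenerate": degenerate})
    return pd.DataFrame(rows)


def spearman_offset_fade(curve: CompletionCurve) -> float:
    """Spearman correlation between |offset| and the completion index."""
    rho, _ = stats.spearmanr(np.abs(curve.offsets), curve.index)
    return float(rho)
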
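"""Literal-definition reference implementations used as independent oracles.

Each function here recomputes a quantity by direct per-pixel / per-row
loops, staying deliberately independent of the vectorised implementations
it is used to check.
"""

import numpy as np


def brute_tpi(values: np.ndarray, half: int) -> np.ndarray:
    """Per-pixel box-window mean subtraction with mirrored edges."""
    pad = np.pad(values, half, mode="symmetric")
    out = np.empty(values.shape, dtype=float)
    rows, cols = values.shape
    side = 2 * half + 1
    for r in range(rows):
        for c in range(cols):
            win = pad[r : r + side, c : c + side]
            out[r, c] = values[r, c] - win.mean()
    return out


def brute_horn(values: np.ndarray, cell: float):
    """Per-pixel Horn 3x3 gradients (east, north), mirrored edges."""
    pad = np.pad(values, 1, mode="symmetric")
    rows, cols = values.shape
    gx = np.empty(values.shape)
    gy = np.empty(values.shape)
    for r in range(rows):
        for c in range(cols):
            z = pad[r : r + 3, c : c + 3]
            east = z[0, 2] + 2 * z[1, 2] + z[2, 2]
            west = z[0, 0] + 2 * z[1, 0] + z[2, 0]
            north = z[0, 0] + 2 * z[0, 1] + z[0, 2]
            south = z[2, 0] + 2 * z[2, 1] + z[2, 2]
            gx[r, c] = (east - west) / (8.0 * cell)
            gy[r, c] = (north - south) / (8.0 * cell)
    return gx, gy


def brute_slope_aspect(values: np.ndarray, cell: float):
    """Slope (deg) and downhill (eastness, northness) from the Horn oracle."""
    gx, gy = brute_horn(values, cell)
    mag = np.hypot(gx, gy)
    slope_deg = np.degrees(np.arctan(mag))
    with np.errstate(invalid="ignore", divide="ignore"):
        a_sin = np.where(mag < 1e-12, 0.0, -gx / mag)
        a_cos = np.where(mag < 1e-12, 0.0, -gy / mag)
    return slope_deg, a_sin, a_cos


def brute_align_nearest(src_vals, src_mask, src_origin, src_cell,
                        tpl_shape, tpl_origin, tpl_cell):
    """Nearest-source-centre lookup by exhaustive distance search."""
    s_rows, s_cols = src_vals.shape
    sx = src_origin[0] + (np.arange(s_cols) + 0.5) * src_cell
    sy = src_origin[1] - (np.arange(s_rows) + 0.5) * src_cell
    out = np.empty(tpl_shape)
    out_mask = np.empty(tpl_shape, dtype=bool)
    for r in range(tpl_shape[0]):
        for c in range(tpl_shape[1]):
            x = tpl_origin[0] + (c + 0.5) * tpl_cell
            y = tpl_origin[1] - (r + 0.5) * tpl_cell
            ci = int(np.argmin(np.abs(sx - x)))
            ri = int(np.argmin(np.abs(sy - y)))
            out[r, c] = src_vals[ri, ci]
            out_mask[r, c] = src_mask[ri, ci]
    return out, out_mask


def brute_ale(predict_proba_closed, X, j, edges):
    """Definition-level first-order ALE: explicit loops over bins and rows.

    Bin b covers (edges[b], edges[b+1]]; the lowest bin also takes its left
    edge.  Returns (centred values, weights).
    """
    X = np.asarray(X, dtype=float)
    n_bins = len(edges) - 1
    local = np.zeros(n_bins)
    weights = np.zeros(n_bins)
    assign = []
    for i in range(X.shape[0]):
        x = X[i, j]
        b = 0
        for k in range(n_bins):
            if (x > edges[k] or k == 0) and x <= edges[k + 1]:
                b = k
                break
        else:
            b = n_bins - 1 if x > edges[-1] else 0
        assign.append(b)
    for b in range(n_bins):
        rows = [i for i, a in enumerate(assign) if a == b]
        weights[b] = len(rows)
        if not rows:
            continue
        diffs = []
        for i in rows:
            hi = X[i].copy()
            lo = X[i].copy()
            hi[j] = edges[b + 1]
            lo[j] = edges[b]
            diffs.append(
                float(predict_proba_closed(hi[None, :])[0])
                - float(predict_proba_closed(lo[None, :])[0])
            )
        local[b] = float(np.mean(diffs))
    acc = np.cumsum(local)
    centred = acc - np.sum(acc * weights) / weights.sum()
    return centred, weights
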
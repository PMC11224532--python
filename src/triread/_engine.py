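"""Numba-compiled inner loops for forward settling and BPTT.

The network state is a single vector of N units partitioned into layers
(`loff`/`lsz` give layer offsets and sizes); weights for all connection
groups live in one flat parameter vector (`goff`/`grows`/`gcols` give
each group's offset and matrix shape, `gsrc`/`gdst` its source and
destination layer).  Biases live in a length-N vector (zero and unused
for layers without incoming connections).

Dynamics are discrete-time synchronous logistic updates: the net input
of a unit at timestep t is the weighted sum of source activations at
t-1 plus its bias.  Layers with incoming connections rest at activation
0.5; input layers (no incoming connections) rest at 0 unless clamped.
Clamped layers are overridden with their clamp pattern at every step of
their clamp window, including the initial state.
"""

import numpy as np
from numba import njit

CRITERION_CE = 0
CRITERION_SSE = 1


@njit(cache=True)
def forward(w, b, goff, grows, gcols, gsrc, gdst, gact,
            loff, lsz, has_in, T, cl_layer, cl_tend, cv, cvoff):
    n_layers = lsz.shape[0]
    N = loff[n_layers]
    acts = np.zeros((T + 1, N), dtype=w.dtype)
    for l in range(n_layers):
        if has_in[l]:
            acts[0, loff[l]:loff[l] + lsz[l]] = 0.5
    for c in range(cl_layer.shape[0]):
        l = cl_layer[c]
        acts[0, loff[l]:loff[l] + lsz[l]] = cv[cvoff[c]:cvoff[c] + lsz[l]]
    net = np.zeros(N, dtype=w.dtype)
    for t in range(1, T + 1):
        for l in range(n_layers):
            if has_in[l]:
                net[loff[l]:loff[l] + lsz[l]] = b[loff[l]:loff[l] + lsz[l]]
        for g in range(gsrc.shape[0]):
            if not gact[g]:
                continue
            W = w[goff[g]:goff[g] + grows[g] * gcols[g]].reshape(
                grows[g], gcols[g])
            a = acts[t - 1, loff[gsrc[g]]:loff[gsrc[g]] + lsz[gsrc[g]]]
            net[loff[gdst[g]]:loff[gdst[g]] + lsz[gdst[g]]] += np.dot(W, a)
        for l in range(n_layers):
            o = loff[l]
            if has_in[l]:
                for i in range(lsz[l]):
                    acts[t, o + i] = 1.0 / (1.0 + np.exp(-net[o + i]))
            else:
                acts[t, o:o + lsz[l]] = acts[t - 1, o:o + lsz[l]]
        for c in range(cl_layer.shape[0]):
            if t <= cl_tend[c]:
                l = cl_layer[c]
                acts[t, loff[l]:loff[l] + lsz[l]] = \
                    cv[cvoff[c]:cvoff[c] + lsz[l]]
    return acts


@njit(cache=True)
def backward(w, acts, goff, grows, gcols, gsrc, gdst, gact, gtrain,
             loff, lsz, has_in, T, cl_layer, cl_tend,
             tl, tgt, win0, win1, criterion):
    """Exact gradients of the window loss w.r.t. weights and biases.

    Returns (gw, gb) in the same flat layouts as (w, b).  Groups with
    gtrain False are skipped during accumulation (their gradient stays
    zero); deltas still propagate through them.
    """
    n_layers = lsz.shape[0]
    n_groups = gsrc.shape[0]
    N = loff[n_layers]
    gw = np.zeros_like(w)
    gb = np.zeros(N, dtype=w.dtype)
    # transposed weight copies so delta propagation runs through BLAS
    wt = np.empty_like(w)
    for g in range(n_groups):
        if not (gact[g] and has_in[gsrc[g]]):
            continue
        rows = grows[g]
        cols = gcols[g]
        base = goff[g]
        for i in range(rows):
            for j in range(cols):
                wt[base + j * rows + i] = w[base + i * cols + j]
    dnets = np.zeros((T + 1, N), dtype=w.dtype)
    da = np.zeros(N, dtype=w.dtype)
    for t in range(T, 0, -1):
        for l in range(n_layers):
            if has_in[l]:
                da[loff[l]:loff[l] + lsz[l]] = 0.0
        if t < T:
            # da[src] += W^T @ dnet[dst] at t+1; layers without incoming
            # connections carry no parameter dependence and are skipped
            for g in range(n_groups):
                if not gact[g] or not has_in[gsrc[g]]:
                    continue
                WT = wt[goff[g]:goff[g] + grows[g] * gcols[g]].reshape(
                    gcols[g], grows[g])
                dn = dnets[t + 1, loff[gdst[g]]:loff[gdst[g]] + grows[g]]
                so = loff[gsrc[g]]
                da[so:so + gcols[g]] += np.dot(WT, dn)
        for l in range(n_layers):
            if not has_in[l]:
                continue
            o = loff[l]
            for i in range(lsz[l]):
                a = acts[t, o + i]
                dnets[t, o + i] = da[o + i] * a * (1.0 - a)
        if win0 <= t <= win1:
            o = loff[tl]
            if criterion == CRITERION_CE:
                for i in range(lsz[tl]):
                    dnets[t, o + i] += acts[t, o + i] - tgt[i]
            else:
                for i in range(lsz[tl]):
                    a = acts[t, o + i]
                    dnets[t, o + i] += 2.0 * (a - tgt[i]) * a * (1.0 - a)
        for c in range(cl_layer.shape[0]):
            if t <= cl_tend[c]:
                l = cl_layer[c]
                dnets[t, loff[l]:loff[l] + lsz[l]] = 0.0
    # weight gradients: one GEMM per trainable group over all timesteps
    for g in range(n_groups):
        if not gact[g] or not gtrain[g]:
            continue
        rows = grows[g]
        cols = gcols[g]
        do = loff[gdst[g]]
        so = loff[gsrc[g]]
        D = np.empty((rows, T), dtype=w.dtype)   # deltas at t = 1..T
        A = np.empty((T, cols), dtype=w.dtype)   # source acts at t-1
        for t in range(1, T + 1):
            for i in range(rows):
                D[i, t - 1] = dnets[t, do + i]
            A[t - 1] = acts[t - 1, so:so + cols]
        G = np.dot(D, A)
        base = goff[g]
        for i in range(rows):
            for j in range(cols):
                gw[base + i * cols + j] = G[i, j]
    for t in range(1, T + 1):
        for l in range(n_layers):
            if has_in[l]:
                o = loff[l]
                for i in range(lsz[l]):
                    gb[o + i] += dnets[t, o + i]
    return gw, gb


@njit(cache=True)
def sgd_update(w, b, gw, gb, wmask, bmask, lr):
    """In-place gradient descent on trainable parameters only."""
    for i in range(w.shape[0]):
        if wmask[i]:
            w[i] -= lr * gw[i]
    for i in range(b.shape[0]):
        if bmask[i]:
            b[i] -= lr * gb[i]
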
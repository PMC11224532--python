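"""The recurrent triangle network: topology, settling, loss, BPTT.

The architecture links orthography (O), phonology (P) and semantics (S)
through hidden layers, giving a direct print-to-sound route
(O -> hidden -> P), a direct print-to-meaning route (O -> hidden -> S)
and mediated routes through the oral-language mappings (P <-> S, each
via its own hidden layer).  Small recurrent cleanup ("attractor") layers
hang off P and S, and a 4-unit context layer reaches S through a 10-unit
hidden layer to disambiguate homophones.

Units are logistic, updated synchronously in discrete timesteps; inputs
are clamped for a trial-specific window and error is injected over a
trial-specific window at the target layer.  Gradients are exact
backpropagation-through-time through the unrolled trial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .errors import ConfigurationError, NumericError
from .lexicon import EncodingSpec

__all__ = [
    "NetworkTopology",
    "WeightSet",
    "TrialSpec",
    "ActivationTrace",
    "Gradients",
    "ORAL_GROUPS",
    "READING_GROUPS",
    "ORAL_BIAS_LAYERS",
    "READING_BIAS_LAYERS",
    "init_network",
    "forward_trial",
    "trial_loss",
    "bptt_gradients",
    "apply_update",
    "train_step",
    "save_weights",
    "load_weights",
]

#: Connection groups trained during the oral-language phase (the
#: phonology/semantics side: oral mappings, both attractor loops and the
#: homophone context path).
ORAL_GROUPS = (
    "phonology->hidden_ps", "hidden_ps->semantics",
    "semantics->hidden_sp", "hidden_sp->phonology",
    "phonology->phon_cleanup", "phon_cleanup->phonology",
    "semantics->sem_cleanup", "sem_cleanup->semantics",
    "context->hidden_ctx", "hidden_ctx->semantics",
)
ORAL_BIAS_LAYERS = ("phonology", "semantics", "hidden_ps", "hidden_sp",
                    "phon_cleanup", "sem_cleanup", "hidden_ctx")

#: Connection groups trained during the reading phase (the
#: orthography-originating routes); everything oral is frozen.
READING_GROUPS = (
    "orthography->hidden_op", "hidden_op->phonology",
    "orthography->hidden_os", "hidden_os->semantics",
)
READING_BIAS_LAYERS = ("hidden_op", "hidden_os")


@dataclass(frozen=True)
class NetworkTopology:
    """Named layer sizes plus directed connection groups.

    ``layers`` preserves insertion order; a connection group is named
    ``"src->dst"``.
    """

    layers: tuple[tuple[str, int], ...]
    connections: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        for s, d in self.connections:
            if s not in names or d not in names:
                raise ValueError(f"connection {s}->{d} references unknown layer")

    @property
    def layer_sizes(self) -> dict[str, int]:
        return dict(self.layers)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(f"{s}->{d}" for s, d in self.connections)

    def incoming(self, layer: str) -> list[str]:
        return [f"{s}->{d}" for s, d in self.connections if d == layer]

    @property
    def input_layers(self) -> tuple[str, ...]:
        dsts = {d for _, d in self.connections}
        return tuple(n for n, _ in self.layers if n not in dsts)

    @property
    def n_units(self) -> int:
        return sum(s for _, s in self.layers)

    @classmethod
    def triangle(cls, spec: EncodingSpec | None = None, *,
                 hidden_op: int = 500, hidden_os: int = 500,
                 hidden_ps: int = 300, hidden_sp: int = 300,
                 attractor: int = 50, context: int = 4,
                 hidden_ctx: int = 10) -> "NetworkTopology":
        """The reading-triangle wiring; defaults give the full-scale
        network (364 O, 200 P, 2,446 S, 500/500/300/300 hidden units,
        50-unit attractors, 4-unit context via a 10-unit hidden layer).
        """
        spec = spec or EncodingSpec.default()
        layers = (
            ("orthography", spec.ortho_len),
            ("phonology", spec.phon_len),
            ("semantics", spec.semantic_dim),
            ("hidden_op", hidden_op),
            ("hidden_os", hidden_os),
            ("hidden_ps", hidden_ps),
            ("hidden_sp", hidden_sp),
            ("phon_cleanup", attractor),
            ("sem_cleanup", attractor),
            ("context", context),
            ("hidden_ctx", hidden_ctx),
        )
        connections = (
            ("orthography", "hidden_op"), ("hidden_op", "phonology"),
            ("orthography", "hidden_os"), ("hidden_os", "semantics"),
            ("phonology", "hidden_ps"), ("hidden_ps", "semantics"),
            ("semantics", "hidden_sp"), ("hidden_sp", "phonology"),
            ("phonology", "phon_cleanup"), ("phon_cleanup", "phonology"),
            ("semantics", "sem_cleanup"), ("sem_cleanup", "semantics"),
            ("context", "hidden_ctx"), ("hidden_ctx", "semantics"),
        )
        return cls(layers=layers, connections=connections)

    @classmethod
    def triangle_scaled(cls, spec: EncodingSpec | None = None,
                        ) -> "NetworkTopology":
        """Desk-scale triangle (~1/5-size hidden and attractor layers)."""
        spec = spec or EncodingSpec.scaled()
        return cls.triangle(spec, hidden_op=100, hidden_os=100,
                            hidden_ps=60, hidden_sp=60, attractor=10)

    # -- compiled wiring (cached) ------------------------------------
    def _compiled(self) -> dict:
        cache = getattr(self, "_wiring", None)
        if cache is not None:
            return cache
        names = [n for n, _ in self.layers]
        sizes = np.array([s for _, s in self.layers], dtype=np.int64)
        loff = np.zeros(len(names) + 1, dtype=np.int64)
        loff[1:] = np.cumsum(sizes)
        lidx = {n: i for i, n in enumerate(names)}
        gsrc = np.array([lidx[s] for s, _ in self.connections], np.int64)
        gdst = np.array([lidx[d] for _, d in self.connections], np.int64)
        grows = sizes[gdst].copy()
        gcols = sizes[gsrc].copy()
        goff = np.zeros(len(self.connections) + 1, dtype=np.int64)
        goff[1:] = np.cumsum(grows * gcols)
        has_in = np.zeros(len(names), dtype=np.bool_)
        for d in gdst:
            has_in[d] = True
        wiring = {
            "names": names, "lidx": lidx, "sizes": sizes, "loff": loff,
            "gsrc": gsrc, "gdst": gdst, "grows": grows, "gcols": gcols,
            "goff": goff, "has_in": has_in,
            "n_params": int(goff[-1]), "n_units": int(loff[-1]),
        }
        object.__setattr__(self, "_wiring", wiring)
        return wiring

    def to_json(self) -> str:
        return json.dumps({"layers": list(map(list, self.layers)),
                           "connections": list(map(list, self.connections))})

    @classmethod
    def from_json(cls, s: str) -> "NetworkTopology":
        d = json.loads(s)
        return cls(layers=tuple((n, int(k)) for n, k in d["layers"]),
                   connections=tuple((a, b) for a, b in d["connections"]))


class WeightSet:
    """Flat weight + bias storage for a topology, with trainable masks.

    ``ws[name]`` returns the (n_dst, n_src) matrix view for a connection
    group; ``ws.bias(layer)`` the bias view of a layer.  Frozen groups
    receive zero gradient and are bit-identical across training steps.
    """

    def __init__(self, topology: NetworkTopology, dtype=np.float32):
        self.topology = topology
        self.dtype = np.dtype(dtype)
        wiring = topology._compiled()
        self.w = np.zeros(wiring["n_params"], dtype=self.dtype)
        self.b = np.zeros(wiring["n_units"], dtype=self.dtype)
        self.trainable_groups: set[str] = set(topology.group_names)
        self.trainable_bias_layers: set[str] = {
            n for n, _ in topology.layers if wiring["has_in"][
                wiring["lidx"][n]]}
        self.meta: dict = {}

    # -- views --------------------------------------------------------
    def _gindex(self, name: str) -> int:
        try:
            return self.topology.group_names.index(name)
        except ValueError:
            raise KeyError(f"unknown connection group {name!r}") from None

    def __getitem__(self, name: str) -> np.ndarray:
        wiring = self.topology._compiled()
        g = self._gindex(name)
        off = wiring["goff"][g]
        return self.w[off:off + wiring["grows"][g] * wiring["gcols"][g]] \
            .reshape(wiring["grows"][g], wiring["gcols"][g])

    def bias(self, layer: str) -> np.ndarray:
        wiring = self.topology._compiled()
        i = wiring["lidx"][layer]
        return self.b[wiring["loff"][i]:wiring["loff"][i]
                      + wiring["sizes"][i]]

    # -- masks --------------------------------------------------------
    def set_trainable(self, groups, bias_layers) -> None:
        self.trainable_groups = set(groups)
        self.trainable_bias_layers = set(bias_layers)

    def _cached_masks(self) -> tuple[np.ndarray, np.ndarray]:
        key = (frozenset(self.trainable_groups),
               frozenset(self.trainable_bias_layers))
        cache = getattr(self, "_mask_cache", None)
        if cache is None or cache[0] != key:
            self._mask_cache = (key, self._masks())
        return self._mask_cache[1]

    def _masks(self) -> tuple[np.ndarray, np.ndarray]:
        wiring = self.topology._compiled()
        wmask = np.zeros(len(self.w), dtype=np.bool_)
        for name in self.trainable_groups:
            g = self._gindex(name)
            off = wiring["goff"][g]
            wmask[off:off + wiring["grows"][g] * wiring["gcols"][g]] = True
        bmask = np.zeros(len(self.b), dtype=np.bool_)
        for layer in self.trainable_bias_layers:
            i = wiring["lidx"][layer]
            bmask[wiring["loff"][i]:wiring["loff"][i]
                  + wiring["sizes"][i]] = True
        return wmask, bmask

    # -- utilities ----------------------------------------------------
    def copy(self) -> "WeightSet":
        ws = WeightSet(self.topology, self.dtype)
        ws.w = self.w.copy()
        ws.b = self.b.copy()
        ws.trainable_groups = set(self.trainable_groups)
        ws.trainable_bias_layers = set(self.trainable_bias_layers)
        ws.meta = dict(self.meta)
        return ws

    def zero_group(self, name: str) -> None:
        self[name][:] = 0.0

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.w.tobytes())
        h.update(self.b.tobytes())
        return h.hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightSet) and \
            self.topology == other.topology and \
            np.array_equal(self.w, other.w) and \
            np.array_equal(self.b, other.b)


def init_network(topology: NetworkTopology, init_range: float = 0.1,
                 seed: int = 0, *, bias_init: float = -1.0,
                 dtype=np.float32) -> WeightSet:
    """Weights i.i.d. uniform in [-init_range, +init_range]; biases of
    layers with incoming connections start at a small negative value so
    units rest near off.  Deterministic per seed."""
    if init_range < 0:
        raise ValueError("init_range must be >= 0")
    rng = np.random.default_rng(seed)
    ws = WeightSet(topology, dtype)
    ws.w[:] = rng.uniform(-init_range, init_range,
                          size=len(ws.w)).astype(dtype)
    wiring = topology._compiled()
    for name, _ in topology.layers:
        if wiring["has_in"][wiring["lidx"][name]]:
            ws.bias(name)[:] = bias_init
    ws.meta = {"seed": int(seed), "init_range": float(init_range),
               "phase": "initialised", "trial_count": 0}
    return ws


@dataclass
class TrialSpec:
    """One presentation: what is clamped, for how long, what the target
    is and over which timesteps error is injected.

    ``clamps`` is a list of (layer, pattern, t_end) triples: the layer's
    activation is overridden with the pattern for timesteps 0..t_end.
    ``window`` is the inclusive (first, last) error-injection timestep.
    """

    clamps: list = field(default_factory=list)
    timesteps: int = 8
    target_layer: str | None = None
    target: np.ndarray | None = None
    window: tuple[int, int] | None = None
    criterion: str = "ce"

    def __post_init__(self) -> None:
        for layer, _, t_end in self.clamps:
            if t_end > self.timesteps:
                raise ValueError(
                    f"clamp on {layer} lasts {t_end} > {self.timesteps} steps")
        if self.window is not None:
            t0, t1 = self.window
            if not 1 <= t0 <= t1 <= self.timesteps:
                raise ValueError("error window must lie within 1..T")
        if self.criterion not in ("ce", "sse"):
            raise ValueError("criterion must be 'ce' or 'sse'")


class ActivationTrace:
    """Per-layer activation vectors for timesteps 0..T (row t holds the
    state after update t; row 0 is the initial/rest state)."""

    def __init__(self, acts: np.ndarray, topology: NetworkTopology):
        self.acts = acts
        self.topology = topology

    @property
    def timesteps(self) -> int:
        return self.acts.shape[0] - 1

    def __getitem__(self, layer: str) -> np.ndarray:
        wiring = self.topology._compiled()
        i = wiring["lidx"][layer]
        return self.acts[:, wiring["loff"][i]:wiring["loff"][i]
                         + wiring["sizes"][i]]

    def window_mean(self, layer: str, window: tuple[int, int]) -> np.ndarray:
        t0, t1 = window
        return self[layer][t0:t1 + 1].mean(axis=0)


@dataclass
class Gradients:
    gw: np.ndarray
    gb: np.ndarray
    topology: NetworkTopology

    def __getitem__(self, name: str) -> np.ndarray:
        wiring = self.topology._compiled()
        g = self.topology.group_names.index(name)
        off = wiring["goff"][g]
        return self.gw[off:off + wiring["grows"][g] * wiring["gcols"][g]] \
            .reshape(wiring["grows"][g], wiring["gcols"][g])

    def bias(self, layer: str) -> np.ndarray:
        wiring = self.topology._compiled()
        i = wiring["lidx"][layer]
        return self.gb[wiring["loff"][i]:wiring["loff"][i]
                       + wiring["sizes"][i]]


def _pack_clamps(weights: WeightSet, trial: TrialSpec):
    wiring = weights.topology._compiled()
    cl_layer = np.array([wiring["lidx"][layer] for layer, _, _ in
                         trial.clamps], dtype=np.int64)
    cl_tend = np.array([t for _, _, t in trial.clamps], dtype=np.int64)
    if trial.clamps:
        cv = np.concatenate([np.asarray(p, dtype=weights.dtype).ravel()
                             for _, p, _ in trial.clamps])
    else:
        cv = np.zeros(0, dtype=weights.dtype)
    cvoff = np.zeros(len(trial.clamps), dtype=np.int64)
    pos = 0
    for c, (layer, p, _) in enumerate(trial.clamps):
        size = int(wiring["sizes"][wiring["lidx"][layer]])
        if len(np.asarray(p).ravel()) != size:
            raise ValueError(f"clamp pattern for {layer} has wrong length")
        cvoff[c] = pos
        pos += size
    # groups whose source is an input layer that carries no signal this
    # trial (unclamped, or clamped all-zero) are skipped entirely
    gact = np.ones(len(wiring["gsrc"]), dtype=np.bool_)
    clamped = {layer: np.any(np.asarray(p)) for layer, p, _ in trial.clamps}
    for g, src in enumerate(wiring["gsrc"]):
        name = wiring["names"][src]
        if not wiring["has_in"][src] and not clamped.get(name, False):
            gact[g] = False
    return cl_layer, cl_tend, cv, cvoff, gact


def forward_trial(weights: WeightSet, trial: TrialSpec) -> ActivationTrace:
    """Run the settling dynamics for one trial and return the trace.

    Raises :class:`NumericError` naming the first offending layer and
    timestep if activations become non-finite.
    """
    wiring = weights.topology._compiled()
    cl_layer, cl_tend, cv, cvoff, gact = _pack_clamps(weights, trial)
    acts = _engine.forward(
        weights.w, weights.b, wiring["goff"], wiring["grows"],
        wiring["gcols"], wiring["gsrc"], wiring["gdst"], gact,
        wiring["loff"], wiring["sizes"], wiring["has_in"],
        trial.timesteps, cl_layer, cl_tend, cv, cvoff)
    if not np.all(np.isfinite(acts)):
        t, u = np.argwhere(~np.isfinite(acts))[0]
        layer = wiring["names"][int(np.searchsorted(
            wiring["loff"], u, side="right") - 1)]
        raise NumericError(
            f"non-finite activation in layer {layer!r} at timestep {t}")
    return ActivationTrace(acts, weights.topology)


#: Activation clipping inside the cross-entropy to avoid log(0).
CE_CLIP = 1e-7


def trial_loss(trace: ActivationTrace, trial: TrialSpec) -> float:
    """Loss summed over target units and error-window timesteps.

    Cross-entropy by default (activations clipped at machine tolerance);
    summed squared error with ``criterion="sse"``.
    """
    if trial.target_layer is None or trial.window is None:
        return 0.0
    t0, t1 = trial.window
    a = trace[trial.target_layer][t0:t1 + 1]
    y = np.asarray(trial.target, dtype=np.float64)
    if trial.criterion == "ce":
        ac = np.clip(a.astype(np.float64), CE_CLIP, 1.0 - CE_CLIP)
        return float(-(y * np.log(ac) + (1.0 - y) * np.log(1.0 - ac)).sum())
    return float(((a.astype(np.float64) - y) ** 2).sum())


def _run_backward(weights: WeightSet, trial: TrialSpec, acts: np.ndarray,
                  gact, cl_layer, cl_tend):
    wiring = weights.topology._compiled()
    gtrain = np.array([name in weights.trainable_groups
                       for name in weights.topology.group_names],
                      dtype=np.bool_)
    if trial.target_layer is None or trial.window is None:
        return (np.zeros_like(weights.w), np.zeros_like(weights.b))
    tl = wiring["lidx"][trial.target_layer]
    tgt = np.asarray(trial.target, dtype=weights.dtype).ravel()
    crit = _engine.CRITERION_CE if trial.criterion == "ce" \
        else _engine.CRITERION_SSE
    return _engine.backward(
        weights.w, acts, wiring["goff"], wiring["grows"], wiring["gcols"],
        wiring["gsrc"], wiring["gdst"], gact, gtrain,
        wiring["loff"], wiring["sizes"], wiring["has_in"],
        trial.timesteps, cl_layer, cl_tend,
        tl, tgt, trial.window[0], trial.window[1], crit)


def bptt_gradients(weights: WeightSet, trial: TrialSpec) -> Gradients:
    """Exact BPTT gradients of :func:`trial_loss` for one trial.

    Frozen (non-trainable) groups and bias layers receive exactly zero
    gradient.  An empty error window yields all-zero gradients.
    """
    wiring = weights.topology._compiled()
    cl_layer, cl_tend, cv, cvoff, gact = _pack_clamps(weights, trial)
    acts = _engine.forward(
        weights.w, weights.b, wiring["goff"], wiring["grows"],
        wiring["gcols"], wiring["gsrc"], wiring["gdst"], gact,
        wiring["loff"], wiring["sizes"], wiring["has_in"],
        trial.timesteps, cl_layer, cl_tend, cv, cvoff)
    gw, gb = _run_backward(weights, trial, acts, gact, cl_layer, cl_tend)
    _, bmask = weights._masks()
    gb = np.where(bmask, gb, 0.0).astype(weights.dtype)
    return Gradients(gw=gw, gb=gb, topology=weights.topology)


def apply_update(weights: WeightSet, gradients: Gradients,
                 learning_rate: float, inplace: bool = False) -> WeightSet:
    """Plain online gradient descent on trainable parameters only."""
    ws = weights if inplace else weights.copy()
    wmask, bmask = ws._masks()
    _engine.sgd_update(ws.w, ws.b, gradients.gw, gradients.gb,
                       wmask, bmask, ws.dtype.type(learning_rate))
    return ws


def train_step(weights: WeightSet, trial: TrialSpec,
               learning_rate: float) -> float:
    """Fused forward + BPTT + in-place update for the training loop;
    returns the trial loss."""
    wiring = weights.topology._compiled()
    cl_layer, cl_tend, cv, cvoff, gact = _pack_clamps(weights, trial)
    acts = _engine.forward(
        weights.w, weights.b, wiring["goff"], wiring["grows"],
        wiring["gcols"], wiring["gsrc"], wiring["gdst"], gact,
        wiring["loff"], wiring["sizes"], wiring["has_in"],
        trial.timesteps, cl_layer, cl_tend, cv, cvoff)
    gw, gb = _run_backward(weights, trial, acts, gact, cl_layer, cl_tend)
    wmask, bmask = weights._cached_masks()
    _engine.sgd_update(weights.w, weights.b, gw, gb, wmask, bmask,
                       weights.dtype.type(learning_rate))
    return trial_loss(ActivationTrace(acts, weights.topology), trial)


def save_weights(weights: WeightSet, path) -> None:
    """Lossless full-precision checkpoint (weights, biases, topology,
    trainable masks and metadata such as phase/trial count/seed)."""
    np.savez(
        path, w=weights.w, b=weights.b,
        topology=np.frombuffer(
            weights.topology.to_json().encode(), dtype=np.uint8),
        meta=np.frombuffer(json.dumps({
            "meta": weights.meta, "dtype": weights.dtype.name,
            "trainable_groups": sorted(weights.trainable_groups),
            "trainable_bias_layers": sorted(weights.trainable_bias_layers),
        }).encode(), dtype=np.uint8))


def load_weights(path, topology: NetworkTopology | None = None) -> WeightSet:
    """Load a checkpoint; raises :class:`ConfigurationError` if the file's
    topology does not match the one supplied."""
    with np.load(path) as z:
        file_topo = NetworkTopology.from_json(bytes(z["topology"]).decode())
        info = json.loads(bytes(z["meta"]).decode())
        if topology is not None and (
                topology.layers != file_topo.layers
                or topology.connections != file_topo.connections):
            raise ConfigurationError(
                "checkpoint topology does not match the requested topology")
        ws = WeightSet(file_topo, dtype=np.dtype(info["dtype"]))
        ws.w[:] = z["w"]
        ws.b[:] = z["b"]
    ws.meta = info["meta"]
    ws.trainable_groups = set(info["trainable_groups"])
    ws.trainable_bias_layers = set(info["trainable_bias_layers"])
    return ws
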
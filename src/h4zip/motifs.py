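"""Combinatorial acetylation state space of the histone H4 N-terminal tail.

The wild-type H4 tail carries four acetylatable lysines (K5, K8, K12, K16).
A *motif* is one combinatorial acetylation pattern over these sites, so the
wild-type state space has 2**4 = 16 motifs; the K16R mutant tail has three
sites and 8 motifs.  Because the in-vitro assay contains no deacetylase,
transitions only ever add an acetyl group: the motifs form a directed
acyclic lattice from the unmodified tail to the fully acetylated one.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "H4_SITES",
    "Motif",
    "Edge",
    "TransitionNetwork",
    "enumerate_motifs",
    "transitions",
    "build_network",
    "restrict_site",
    "motifs_containing",
    "parse_motif_label",
]

#: H4 tail lysines in N-terminal -> internal order.  Extra labels beyond the
#: canonical four support small test lattices, not biology.
H4_SITES: tuple[str, ...] = ("K5", "K8", "K12", "K16", "K20", "K31")

_LABEL_RE = re.compile(r"K\d+ac")


@dataclass(frozen=True)
class Motif:
    """One acetylation pattern: a bit per site (1 = acetylated)."""

    bits: tuple[int, ...]
    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.sites):
            raise ValueError("bit-vector length must equal number of sites")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site labels must be unique")

    @property
    def acetyl_count(self) -> int:
        return sum(self.bits)

    @property
    def acetylated_sites(self) -> tuple[str, ...]:
        return tuple(s for s, b in zip(self.sites, self.bits) if b)

    @property
    def free_sites(self) -> tuple[str, ...]:
        return tuple(s for s, b in zip(self.sites, self.bits) if not b)

    @property
    def label(self) -> str:
        """Canonical label: "unmod" or N-terminal->internal "K..ac" concatenation."""
        if self.acetyl_count == 0:
            return "unmod"
        return "".join(f"{s}ac" for s in self.acetylated_sites)

    def with_site(self, site: str) -> "Motif":
        """Return the motif with one additional acetylated site."""
        i = self.sites.index(site)
        if self.bits[i]:
            raise ValueError(f"site {site} is already acetylated in {self.label}")
        bits = list(self.bits)
        bits[i] = 1
        return Motif(tuple(bits), self.sites)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_motif_label(label: str, sites: tuple[str, ...] = H4_SITES[:4]) -> Motif:
    """Parse a canonical motif label back into a :class:`Motif`.

    Accepts "unmod", concatenations like "K12acK16ac" in any order, and the
    "tetra-ac" alias for the fully acetylated pattern.
    """
    label = label.strip()
    if label in ("unmod", "unmodified"):
        return Motif((0,) * len(sites), sites)
    if label == "tetra-ac":
        return Motif((1,) * len(sites), sites)
    tokens = _LABEL_RE.findall(label)
    if not tokens or "".join(tokens) != label:
        raise ValueError(f"unparseable motif label: {label!r}")
    bits = [0] * len(sites)
    for tok in tokens:
        site = tok[:-2]
        if site not in sites:
            raise ValueError(f"unknown site {site!r} in label {label!r}")
        bits[sites.index(site)] = 1
    return Motif(tuple(bits), sites)


def enumerate_motifs(n_sites: int, sites: tuple[str, ...] | None = None) -> list[Motif]:
    """All 2**n_sites motifs in canonical order.

    Canonical order is by acetyl count ascending, then lexicographically by
    the tuple of acetylated site indices — the reading order of the
    experiment's motif heatmaps, and stable across runs.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if sites is None:
        if n_sites > len(H4_SITES):
            raise ValueError(f"no default labels for {n_sites} sites; pass `sites`")
        sites = H4_SITES[:n_sites]
    elif len(sites) != n_sites:
        raise ValueError("len(sites) must equal n_sites")

    motifs = []
    for count in range(n_sites + 1):
        for idx in itertools.combinations(range(n_sites), count):
            bits = tuple(1 if i in idx else 0 for i in range(n_sites))
            motifs.append(Motif(bits, tuple(sites)))
    return motifs


def transitions(m: Motif) -> list[tuple[Motif, str]]:
    """Single-site acetylation moves from ``m``: one per free site."""
    return [(m.with_site(s), s) for s in m.free_sites]


@dataclass(frozen=True)
class Edge:
    """A single acetylation event: ``source`` gains an acetyl at ``site``."""

    source: Motif
    target: Motif
    site: str


@dataclass(frozen=True)
class TransitionNetwork:
    """The acetylation lattice: motifs plus all single-site acetylation edges."""

    sites: tuple[str, ...]
    motifs: tuple[Motif, ...] = field(repr=False)
    edges: tuple[Edge, ...] = field(repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, m: Motif | str) -> int:
        label = m if isinstance(m, str) else m.label
        try:
            return self._label_index[label]
        except KeyError:
            raise KeyError(f"motif {label!r} not in network") from None

    @property
    def _label_index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        cache = object.__getattribute__(self, "__dict__").get("_idx")
        if cache is None:
            cache = {m.label: i for i, m in enumerate(self.motifs)}
            object.__getattribute__(self, "__dict__")["_idx"] = cache
        return cache

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.motifs]


def build_network(sites: tuple[str, ...] = H4_SITES[:4]) -> TransitionNetwork:
    """Build the full acetylation lattice over ``sites``."""
    motifs = enumerate_motifs(len(sites), tuple(sites))
    edges = tuple(
        Edge(m, target, site) for m in motifs for target, site in transitions(m)
    )
    return TransitionNetwork(tuple(sites), tuple(motifs), edges)


def restrict_site(net: TransitionNetwork, site: str) -> TransitionNetwork:
    """Sub-network over motifs with ``site`` unacetylated (site disabled).

    Equivalent to the lattice on the remaining sites; used for the K16R
    counterfactual where every reaction involving K16 is removed.
    """
    if site not in net.sites:
        raise ValueError(f"site {site!r} not in network sites {net.sites}")
    remaining = tuple(s for s in net.sites if s != site)
    return build_network(remaining)


def motifs_containing(net: TransitionNetwork, site: str) -> list[Motif]:
    """Motifs of the network in which ``site`` is acetylated."""
    if site not in net.sites:
        return []
    i = net.sites.index(site)
    return [m for m in net.motifs if m.bits[i]]
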
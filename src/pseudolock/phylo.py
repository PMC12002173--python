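"""Rooted phylogeny container with edges addressed by child node.

The tree is stored as parent/children maps over unique string labels.
Unlabeled internal nodes are auto-named ``nK`` where ``K`` is the node's
preorder index, so the naming is stable across reruns of the same input.
Every edge is identified by the label of its child node; the root label
doubles as the identifier of a *virtual root edge* hanging above the root,
which lets a character gain be placed above the whole tree.

Polytomies are allowed. Branch lengths are optional and, when present,
must be nonnegative.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import dendropy

from .errors import InvalidArgumentError, NewickParseError, NotFoundError

__all__ = ["Phylogeny", "read_newick", "write_newick"]


class Phylogeny:
    """A rooted tree over uniquely labeled nodes.

    Parameters
    ----------
    parent
        Map child label -> parent label for every non-root node.
    root
        Label of the unique root node.
    branch_lengths
        Optional map child label -> length of the edge above it.
    """

    def __init__(
        self,
        parent: Mapping[str, str],
        root: str,
        branch_lengths: Mapping[str, float] | None = None,
    ) -> None:
        self.root = root
        self._parent: dict[str, str | None] = {root: None}
        children: dict[str, list[str]] = {root: []}
        for child, par in parent.items():
            if child == root:
                raise InvalidArgumentError("root cannot have a parent")
            self._parent[child] = par
            children.setdefault(child, [])
            children.setdefault(par, []).append(child)
        # parents must themselves be reachable nodes
        for par in set(parent.values()):
            if par != root and par not in parent:
                raise InvalidArgumentError(
                    f"node {par!r} is a parent but has no parent entry and is not the root"
                )
        self._children = {k: tuple(v) for k, v in children.items()}
        self.branch_lengths: dict[str, float] = dict(branch_lengths or {})
        for node, bl in self.branch_lengths.items():
            if bl < 0:
                raise InvalidArgumentError(f"negative branch length on edge {node!r}")
        self._preorder = self._compute_preorder()
        if len(self._preorder) != len(self._parent):
            raise InvalidArgumentError("tree contains a cycle or unreachable nodes")
        self._postorder = list(reversed(self._preorder))
        self._tips = tuple(n for n in self._preorder if not self._children[n])
        self._tipset = frozenset(self._tips)

    # -- construction ------------------------------------------------------

    def _compute_preorder(self) -> list[str]:
        order: list[str] = []
        stack = [self.root]
        seen: set[str] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                raise InvalidArgumentError("duplicate node label or cycle")
            seen.add(node)
            order.append(node)
            stack.extend(reversed(self._children.get(node, ())))
        return order

    # -- basic queries -----------------------------------------------------

    @property
    def tips(self) -> tuple[str, ...]:
        return self._tips

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node labels in preorder."""
        return tuple(self._preorder)

    def is_tip(self, node: str) -> bool:
        return node in self._tipset

    def parent(self, node: str) -> str | None:
        try:
            return self._parent[node]
        except KeyError:
            raise NotFoundError(f"node {node!r} not in tree") from None

    def children(self, node: str) -> tuple[str, ...]:
        try:
            return self._children[node]
        except KeyError:
            raise NotFoundError(f"node {node!r} not in tree") from None

    def __contains__(self, node: str) -> bool:
        return node in self._parent

    def __len__(self) -> int:
        return len(self._parent)

    def preorder(self) -> Iterator[str]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[str]:
        return iter(self._postorder)

    def edges(self) -> Iterator[str]:
        """Edge identifiers: every node label including the virtual root edge."""
        return iter(self._preorder)

    def has_edge(self, edge: str) -> bool:
        return edge in self._parent

    # -- topology helpers --------------------------------------------------

    def subtree_nodes(self, node: str) -> list[str]:
        if node not in self._parent:
            raise NotFoundError(f"node {node!r} not in tree")
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def subtree_tips(self, node: str) -> list[str]:
        return [n for n in self.subtree_nodes(node) if n in self._tipset]

    def ancestors(self, node: str) -> Iterator[str]:
        """Strict ancestors, from parent up to the root."""
        cur = self.parent(node)
        while cur is not None:
            yield cur
            cur = self._parent[cur]

    def is_ancestor(self, anc: str, node: str) -> bool:
        """True when ``anc`` lies on the path from ``node``'s parent to the root."""
        return any(a == anc for a in self.ancestors(node))

    def mrca(self, labels: Iterable[str]) -> str:
        labels = list(labels)
        if not labels:
            raise InvalidArgumentError("mrca of an empty label set")
        for lab in labels:
            if lab not in self._parent:
                raise NotFoundError(f"node {lab!r} not in tree")
        paths = []
        for lab in labels:
            path = [lab, *self.ancestors(lab)]
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                mrca = level[0]
            else:
                break
        return mrca

    # -- serialization -----------------------------------------------------

    def to_newick(self, comments: Mapping[str, str] | None = None) -> str:
        """Write Newick; ``comments`` maps node label -> bracketed comment text
        emitted after the label (used for per-edge event annotations)."""
        comments = comments or {}

        def render(node: str) -> str:
            parts = ""
            kids = self._children[node]
            if kids:
                parts = "(" + ",".join(render(k) for k in kids) + ")"
            label = node
            com = f"[{comments[node]}]" if node in comments else ""
            bl = self.branch_lengths.get(node)
            bls = f":{bl:g}" if bl is not None else ""
            return f"{parts}{label}{com}{bls}"

        return render(self.root) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string into a :class:`Phylogeny`.

    Unlabeled internal nodes are named ``nK`` by preorder index; a label
    collision with an existing node is an error. Malformed input raises
    :class:`NewickParseError` carrying the parser's line/column report.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several reader error classes
        raise NewickParseError(str(exc)) from exc

    labels: dict[int, str] = {}
    used: set[str] = set()
    for idx, nd in enumerate(dtree.preorder_node_iter()):
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None or label == "":
            label = f"n{idx}"
        if label in used:
            raise NewickParseError(f"duplicate node label {label!r}")
        used.add(label)
        labels[id(nd)] = label

    parent: dict[str, str] = {}
    blens: dict[str, float] = {}
    root_label = labels[id(dtree.seed_node)]
    for nd in dtree.preorder_node_iter():
        lab = labels[id(nd)]
        if nd.parent_node is not None:
            parent[lab] = labels[id(nd.parent_node)]
        if nd.edge.length is not None and nd.parent_node is not None:
            blens[lab] = float(nd.edge.length)
    return Phylogeny(parent, root_label, blens)


def write_newick(tree: Phylogeny, comments: Mapping[str, str] | None = None) -> str:
    return tree.to_newick(comments)
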
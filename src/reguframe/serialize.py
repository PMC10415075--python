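"""DOT export for networks and policy trees (deterministic node ordering,
plain Graphviz text; rendering is left to external tooling)."""

from __future__ import annotations

from pathlib import Path

from reguframe.bayesnet import DiscreteNet
from reguframe.policy import PolicyTree


def _quote(s: str) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def net_to_dot(net: DiscreteNet) -> str:
    lines = ["digraph network {", "  rankdir=LR;"]
    for v in sorted(net.nodes):
        shape = "box" if v == net.frame_var else ("doublecircle" if v == net.target else "ellipse")
        lines.append(f"  {_quote(v)} [shape={shape}];")
    edges = sorted((p, v) for v in net.nodes for p in net.parents[v])
    for p, v in edges:
        lines.append(f"  {_quote(p)} -> {_quote(v)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def tree_to_dot(tree: PolicyTree) -> str:
    lines = ["digraph policy {", "  node [shape=box];"]
    counter = [0]

    def rec(node: PolicyTree) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if node.kind == "send":
            lines.append(f"  {nid} [label={_quote('send ' + node.label)} shape=oval];")
            return nid
        lines.append(f"  {nid} [label={_quote('ask ' + node.label)}];")
        for state in sorted(node.children):
            cid = rec(node.children[state])
            lines.append(f"  {nid} -> {cid} [label={_quote(state)}];")
        return nid

    rec(tree)
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot(obj: DiscreteNet | PolicyTree, path: str | Path) -> None:
    """Write a network or policy tree as a Graphviz DOT file."""
    if isinstance(obj, DiscreteNet):
        text = net_to_dot(obj)
    elif isinstance(obj, PolicyTree):
        text = tree_to_dot(obj)
    else:
        raise TypeError(f"cannot export {type(obj).__name__} as DOT")
    Path(path).write_text(text)
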
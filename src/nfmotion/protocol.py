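"""Session protocol: ordered blocks of labelled, contiguous segments.

The default template mirrors the single-session design: a baseline block
(60 s rest, foot-stomping task, 35 s rest, pronation-supination task),
three neurofeedback training blocks (60 s rest + 60 s downregulation),
then one movement block per task (rest, pre task, 35 s rest, 60 s
neurofeedback, post task). Task-window durations are not fixed by the
protocol and default to 10 s.

Segment labels are ``"<block>_<phase>"``; the segment ``"<block>_rest"``
is the block's initial rest period used for power normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = ["ProtocolSegment", "ProtocolBlock", "SessionProtocol", "default_protocol"]


@dataclass(frozen=True)
class ProtocolSegment:
    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"segment {self.label!r} has non-positive duration")


@dataclass(frozen=True)
class ProtocolBlock:
    name: str
    segments: Tuple[ProtocolSegment, ...]


@dataclass(frozen=True)
class SessionProtocol:
    blocks: Tuple[ProtocolBlock, ...]

    def __post_init__(self) -> None:
        labels = [s.label for b in self.blocks for s in b.segments]
        if len(labels) != len(set(labels)):
            raise ValueError("segment labels must be unique across the session")
        names = [b.name for b in self.blocks]
        if "fs" in names and "hps" in names and names.index("fs") > names.index("hps"):
            raise ValueError("the FS block must precede the HPS block")

    def windows(self) -> List[Tuple[str, float, float]]:
        """Absolute half-open [start, end) windows, tiling the session."""
        out = []
        t = 0.0
        for block in self.blocks:
            for seg in block.segments:
                out.append((seg.label, t, t + seg.duration_s))
                t += seg.duration_s
        return out

    def window(self, label: str) -> Tuple[float, float]:
        for lab, t0, t1 in self.windows():
            if lab == label:
                return (t0, t1)
        raise KeyError(f"no segment labelled {label!r}")

    @property
    def duration(self) -> float:
        return sum(s.duration_s for b in self.blocks for s in b.segments)

    def block_of(self, label: str) -> str:
        for block in self.blocks:
            if any(s.label == label for s in block.segments):
                return block.name
        raise KeyError(f"no segment labelled {label!r}")

    def to_dict(self) -> Dict:
        return {
            "blocks": [
                {
                    "name": b.name,
                    "segments": [
                        {"label": s.label, "duration_s": s.duration_s}
                        for s in b.segments
                    ],
                }
                for b in self.blocks
            ]
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "SessionProtocol":
        blocks = []
        for b in d["blocks"]:
            segs = tuple(
                ProtocolSegment(label=s["label"], duration_s=float(s["duration_s"]))
                for s in b["segments"]
            )
            blocks.append(ProtocolBlock(name=b["name"], segments=segs))
        return cls(blocks=tuple(blocks))


def default_protocol(task_s: float = 10.0) -> SessionProtocol:
    """The four-block session template with configurable task durations."""

    def seg(label: str, dur: float) -> ProtocolSegment:
        return ProtocolSegment(label, dur)

    blocks = [
        ProtocolBlock(
            "baseline",
            (
                seg("baseline_rest", 60.0),
                seg("baseline_fs", task_s),
                seg("baseline_interrest", 35.0),
                seg("baseline_hps", task_s),
            ),
        ),
    ]
    for i in (1, 2, 3):
        blocks.append(
            ProtocolBlock(
                f"nf{i}",
                (seg(f"nf{i}_rest", 60.0), seg(f"nf{i}_down", 60.0)),
            )
        )
    for task in ("fs", "hps"):
        blocks.append(
            ProtocolBlock(
                task,
                (
                    seg(f"{task}_rest", 60.0),
                    seg(f"{task}_pre", task_s),
                    seg(f"{task}_interrest", 35.0),
                    seg(f"{task}_nf", 60.0),
                    seg(f"{task}_post", task_s),
                ),
            )
        )
    return SessionProtocol(blocks=tuple(blocks))
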
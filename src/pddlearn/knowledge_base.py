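"""The three-space knowledge base linking units, patterns, and records.

The Knowledge Space lists the DSUs (their three-part codes and class
associations), the Pattern Space lists each DSU's summarized and
comprehensive patterns with their targets, and the Data Space is the
records x DSUs matrix of comprehensive-pattern possession counts.  A
record can thus be traced to *what* patterns it possesses, *why* (which
disentangled unit they came from), and *how* (which entity cluster the
pattern covers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .disentangle import DSU
from .patterns import ComprehensivePattern, PatternCounts, _code_str

__all__ = ["KnowledgeBase", "assemble", "export", "load"]

_PATTERN_SEP = ";"


def _avs_to_str(av_pairs) -> str:
    return _PATTERN_SEP.join(f"{a}={c}" for a, c in av_pairs)


def _str_to_avs(s: str) -> tuple:
    if not s:
        return ()
    return tuple(tuple(part.split("=", 1)) for part in s.split(_PATTERN_SEP))


@dataclass
class KnowledgeBase:
    knowledge_space: list          # DSU objects
    pattern_space: dict            # code -> list[ComprehensivePattern]
    data_space: PatternCounts
    config: dict = field(default_factory=dict)

    @property
    def class_map(self) -> dict:
        return {d.code: d.class_assoc for d in self.knowledge_space}

    def dsu(self, code: tuple) -> DSU:
        for d in self.knowledge_space:
            if tuple(d.code) == tuple(code):
                return d
        raise KeyError(f"no DSU with code {code}")

    def trace(self, record_id) -> dict:
        """Per-record what/why/how query."""
        out = {}
        for d in self.knowledge_space:
            code = tuple(d.code)
            cnt = self.data_space.count(record_id, code)
            if cnt <= 0:
                continue
            possessed = [
                p for p in self.pattern_space.get(code, ())
                if record_id in p.support
            ]
            out[code] = {
                "class_assoc": d.class_assoc,
                "n_patterns": cnt,
                "patterns": [_avs_to_str(p.av_pairs) for p in possessed],
                "entity_cluster_size": len(d.entities),
            }
        return out


def assemble(
    dsus: list[DSU],
    patterns_by_dsu: dict,
    counts: PatternCounts,
    config: dict | None = None,
) -> KnowledgeBase:
    """Link the three spaces, rejecting dangling DSU codes."""
    known = {tuple(d.code) for d in dsus}
    for code in patterns_by_dsu:
        if tuple(code) not in known:
            raise ValueError(f"pattern space references unknown DSU {code}")
    count_codes = set(counts.record_counts.columns)
    known_strs = {_code_str(c) for c in known}
    dangling = count_codes - known_strs
    if dangling:
        raise ValueError(f"data space references unknown DSU(s) {sorted(dangling)}")
    return KnowledgeBase(
        knowledge_space=list(dsus),
        pattern_space={tuple(k): list(v) for k, v in patterns_by_dsu.items()},
        data_space=counts,
        config=dict(config or {}),
    )


def export(kb: KnowledgeBase, directory) -> dict:
    """Write knowledge_space.tsv, pattern_space.tsv, data_space.csv,
    manifest.json into ``directory``; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    krows = [
        {
            "pc": d.code[0],
            "group": d.code[1],
            "subgroup": d.code[2],
            "class_assoc": d.class_assoc if d.class_assoc is not None else "",
            "summarized_pattern": _avs_to_str(d.summarized_pattern),
            "n_entities": len(d.entities),
        }
        for d in kb.knowledge_space
    ]
    prows = [
        {
            "dsu_code": _code_str(code),
            "pattern": _avs_to_str(p.av_pairs),
            "support": len(p.support),
            "significance": round(p.significance, 10),
            "target": kb.class_map.get(tuple(code)) or "",
        }
        for code, plist in sorted(kb.pattern_space.items())
        for p in plist
    ]
    paths = {
        "knowledge_space": directory / "knowledge_space.tsv",
        "pattern_space": directory / "pattern_space.tsv",
        "data_space": directory / "data_space.csv",
        "manifest": directory / "manifest.json",
    }
    pd.DataFrame(
        krows,
        columns=["pc", "group", "subgroup", "class_assoc",
                 "summarized_pattern", "n_entities"],
    ).to_csv(paths["knowledge_space"], sep="\t", index=False)
    pd.DataFrame(
        prows, columns=["dsu_code", "pattern", "support", "significance", "target"]
    ).to_csv(paths["pattern_space"], sep="\t", index=False)
    kb.data_space.record_counts.to_csv(paths["data_space"], index_label="record_id")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "config": kb.config,
                "cp_totals": {
                    _code_str(c): int(n) for c, n in kb.data_space.cp_totals.items()
                },
            },
            fh,
            indent=2,
            default=str,
        )
    return paths


def load(directory) -> KnowledgeBase:
    """Rebuild a knowledge base from an exported directory.

    Entity sets and pattern supports are restored only as record-count
    information present in the files (support sizes, entity counts live
    in the TSVs); the three spaces round-trip exactly.
    """
    directory = Path(directory)
    kdf = pd.read_csv(directory / "knowledge_space.tsv", sep="\t",
                      keep_default_na=False)
    pdf = pd.read_csv(directory / "pattern_space.tsv", sep="\t",
                      keep_default_na=False)
    counts = pd.read_csv(directory / "data_space.csv").set_index("record_id")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    dsus = []
    for _, row in kdf.iterrows():
        pattern = _str_to_avs(row["summarized_pattern"])
        dsus.append(
            DSU(
                code=(int(row["pc"]), int(row["group"]), int(row["subgroup"])),
                members=[],
                summarized_pattern=list(pattern),
                entities=frozenset(range(int(row["n_entities"]))),
                class_assoc=row["class_assoc"] or None,
            )
        )
    patterns_by_dsu: dict = {tuple(d.code): [] for d in dsus}
    for _, row in pdf.iterrows():
        code = tuple(int(c) for c in str(row["dsu_code"]).split("."))
        patterns_by_dsu[code].append(
            ComprehensivePattern(
                dsu_code=code,
                avs=(),
                av_pairs=_str_to_avs(row["pattern"]),
                support=frozenset(range(int(row["support"]))),
                significance=float(row["significance"]),
            )
        )
    totals = {
        tuple(int(c) for c in k.split(".")): v
        for k, v in manifest["cp_totals"].items()
    }
    pc = PatternCounts(cp_totals=totals, record_counts=counts)
    return KnowledgeBase(
        knowledge_space=dsus,
        pattern_space=patterns_by_dsu,
        data_space=pc,
        config=manifest.get("config", {}),
    )
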
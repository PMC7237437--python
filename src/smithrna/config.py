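"""Flat key-value pipeline configuration.

Defaults reproduce the published thresholds exactly: cluster size > 200,
modal-end sharpness fractions 0.75/0.75, seed on centroid nt 4-10, at least
11 matches, ddG < -9, dG < -20 (model-native kcal/mol), forced duplex helix
3-10, diversity window 10 with step 5, clustering identity 0.99, at most 1
mapping mismatch, 70-bp pre region, folding temperature metadata 25 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    # mapping / clustering (requirements 1-2)
    max_mismatch: int = 1
    identity: float = 0.99
    min_cluster_size: int = 200
    min_frac5: float = 0.75
    min_frac3: float = 0.75
    # target prediction (requirements 3-6)
    seed_start: int = 4
    seed_end: int = 10
    min_matches: int = 11
    max_ddg: float = -9.0
    max_dg: float = -20.0
    helix_start: int = 3
    helix_end: int = 10
    context: int = 30
    flank5: int = 3
    flank3: int = 15
    fold_window: int = 140
    # annotation
    pre_length: int = 70
    fold_temperature: float = 25.0
    species: str = "SynT"
    sex: str = "F"
    # diversity
    window_size: int = 10
    window_step: int = 5
    ordered_pairs: bool = False
    # files
    genome_fasta: str = ""
    annotation_gff3: str = ""
    reads_fastq: str = ""
    nuclear_fasta: str = ""
    utr_fasta: str = ""
    alignment_fasta: str = ""
    regions_tsv: str = ""
    assay_tsv: str = ""
    out_prefix: str = "smithrna_out"
    # randomness
    seed: int = 0

    def to_thresholds(self):
        from .targets import Thresholds

        return Thresholds(
            min_matches=self.min_matches, max_ddg=self.max_ddg, max_dg=self.max_dg,
            seed=(self.seed_start, self.seed_end),
            forced_helix=(self.helix_start, self.helix_end),
            context=self.context, flank5=self.flank5, flank3=self.flank3,
            fold_window=self.fold_window,
        )

    def serialize(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.serialize())

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                k, v = line.split("=", 1)
                values[k.strip()] = v.strip()
        return cls.from_dict(values)

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if isinstance(raw, str):
                if f.type in ("int", int):
                    raw = int(raw)
                elif f.type in ("float", float):
                    raw = float(raw)
                elif f.type in ("bool", bool):
                    raw = raw.lower() in ("1", "true", "yes")
            kwargs[f.name] = raw
        unknown = set(values) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)
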
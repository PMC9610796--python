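"""Flat run configuration shared by the CLI subcommands.

One key/value file (``key = value`` per line, ``#`` comments) carries every
tunable threshold; unknown keys are rejected so typos fail loudly, and all
values are echoed into each run's manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    # ORF calling / annotation
    min_codons: int = 50
    max_overlap: int = 75
    usage_llr_threshold: float = 0.0
    # promoter scan
    window: int = 200
    # variants
    min_freq: float = 0.10
    af_field: str = "AF"
    # hr detection
    unit_min: int = 40
    unit_max: int = 80
    hr_min_units: int = 2
    hr_max_units: int = 6
    max_unit_divergence: float = 0.25
    kmer: int = 10
    cluster_gap: int = 250
    palindrome_min_arm: int = 4
    palindrome_max_mismatches: int = 2
    # distances / phylogeny
    demarcation: float = 0.050
    gamma: float | None = None
    kappa: float = 2.0
    bootstrap: int = 500
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                ftype = known[key].type
                if value.lower() in ("none", ""):
                    kwargs[key] = None
                elif "int" in str(ftype):
                    kwargs[key] = int(value)
                elif "float" in str(ftype):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)
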
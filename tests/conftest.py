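import numpy as np
import pytest

from chipscope import ChipWhitelist, SimConfig, VariantCall


@pytest.fixture
def toy_whitelist() -> ChipWhitelist:
    """Two-gene whitelist: any truncating DNMT3A variant; two listed TET2
    protein changes."""
    return ChipWhitelist.from_entries(
        [
            ("DNMT3A", "any_truncating", []),
            ("TET2", "listed_protein_changes", ["p.C1135Y", "p.R1261H"]),
        ]
    )


@pytest.fixture
def toy_calls() -> list[VariantCall]:
    """Six variants; exactly three satisfy the toy whitelist rules."""
    mk = lambda sid, gene, pc, alt=30, ref=70, pos=100: VariantCall(
        sample_id=sid, chrom="2", pos=pos, ref="C", alt="T", gene=gene,
        protein_change=pc, ref_reads=ref, alt_reads=alt
    )
    return [
        mk("S1", "DNMT3A", "p.W581*"),          # CHIP: truncating
        mk("S1", "DNMT3A", "p.R882H"),          # not: missense, no rule match
        mk("S2", "TET2", "p.C1135Y"),           # CHIP: listed change
        mk("S2", "TET2", "p.A1000T"),           # not: unlisted change
        mk("S3", "JAK2", "p.V617F"),            # not: gene absent
        mk("S3", "DNMT3A", "p.L723fs"),         # CHIP: frameshift
    ]


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=7)
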
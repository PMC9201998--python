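import numpy as np
import pytest

from admixscan.synthetic_admix import SimConfig, SweepSpec, simulate_study


@pytest.fixture(scope="session")
def neutral_study():
    """Small admixed study without sweeps, shared across read-only tests."""
    return simulate_study(SimConfig(n_snps=800, n_chrom=2, n_per_pop=20, alpha=0.3, seed=11))


@pytest.fixture(scope="session")
def swept_study():
    """Admixed study with one planted hard sweep in the hybrid population."""
    spec = SweepSpec(chrom="1", pos_bp=5_000_000, carrier_fraction=0.9,
                     core_span_bp=500_000, target_pop="HYB")
    return simulate_study(SimConfig(seed=42, sweep_specs=[spec]))


@pytest.fixture(scope="session")
def drifted_study():
    """Admixed study bred in a small pool: strong drift gives the wide local-
    ancestry variance needed to see f_dM track true ancestry."""
    return simulate_study(
        SimConfig(n_snps=800, n_chrom=2, n_per_pop=20, pool_size=20, alpha=0.3, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_vcf(path, lines):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n##contig=<ID=2>\n"
    )
    path.write_text(header + "\n".join(lines) + "\n")
    return path


def make_popmap(path, entries):
    path.write_text("".join(f"{s}\t{p}\t{r}\n" for s, p, r in entries))
    return path
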
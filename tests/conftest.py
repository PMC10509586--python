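import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crypticsex.genotype_io import MISSING, GenotypeMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(dosage, chrom=None, pos=None, **kwargs) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array with minimal
    single-chromosome metadata (test helper)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "ref": ["A"] * m, "alt": ["T"] * m,
        "site_depth": np.full(m, 30.0),
        "n_alt": np.ones(m, dtype=np.int32),
    })
    samples = kwargs.pop("samples", [f"s{i}" for i in range(n)])
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, **kwargs)


def write_test_vcf(path, samples, records):
    """Write a small VCF by hand.  Each record is a dict with keys
    chrom, pos, ref, alt (comma string), qual, dp (INFO depth) and
    gts — a list of per-sample cells like '0/1' or '0/1:45' (GT[:GQ])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">\n')
        chroms = dict.fromkeys(r["chrom"] for r in records)
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in records:
            has_gq = any(":" in g for g in r["gts"])
            fmt = "GT:GQ" if has_gq else "GT"
            info = f"DP={r['dp']}" if r.get("dp") is not None else "."
            cells = [g if (":" in g or not has_gq) else g + ":99"
                     for g in r["gts"]]
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
                     f"{r.get('qual', 100)}\tPASS\t{info}\t{fmt}\t"
                     + "\t".join(cells) + "\n")
    return path


@pytest.fixture(scope="session")
def strict_sim():
    """Strict parthenogenesis, two founder clones, no mutation."""
    from crypticsex import preset_config, run_simulation
    cfg = preset_config("strict", seed=11, mutation_rate=0.0,
                        pop_size=100, n_sites=1200, n_x_sites=24)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def rare_sex_sim():
    """Rare sexual reproduction via occasional X-loss males."""
    from crypticsex import preset_config, run_simulation
    cfg = preset_config("rare-sex", seed=12, n_sites=1200, n_x_sites=24)
    return run_simulation(cfg)
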
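import pytest

from cgdseek.synthetic_population import build_proband_family_fixture


@pytest.fixture(scope="session")
def family_bundle(tmp_path_factory):
    """The seven-member discovery family, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("family")
    pedigree, calls, freqs = build_proband_family_fixture(outdir)
    return {
        "pedigree": pedigree,
        "calls": calls,
        "freqs": freqs,
        "vcf": outdir / "family.vcf",
        "ped": outdir / "family.ped",
        "freq_tsv": outdir / "freqs.tsv",
        "dir": outdir,
    }
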
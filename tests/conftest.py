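import pytest

from pseudotrace import LesionReport, concatenate_gene, scan_gene
from pseudotrace.demo import GRISON, REFERENCE_TAXA, WEASEL, build_bundle


@pytest.fixture(scope="session")
def bundle():
    return build_bundle(seed=0)


@pytest.fixture(scope="session")
def demo_views(bundle):
    return {
        gene: concatenate_gene(bundle.alignments[gene], bundle.models[gene])
        for gene in ("TAS1R1", "TAS1R3")
    }


@pytest.fixture(scope="session")
def demo_reports(demo_views):
    """Scanned reports for both targets plus empty reports for the
    jointly-aligned functional references (observed intact)."""
    reports = {}
    for gene, view in demo_views.items():
        reps = [scan_gene(view, target=t) for t in (WEASEL, GRISON)]
        reps += [LesionReport(taxon=t, gene=gene) for t in REFERENCE_TAXA]
        reports[gene] = reps
    return reports
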
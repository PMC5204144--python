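from __future__ import annotations

import dendropy
import numpy as np
import pytest

from phylodemog.phylo_signal import PhyloCovariance, phylo_vcv


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             preserve_underscores=True)


@pytest.fixture
def balanced4() -> PhyloCovariance:
    """((A:1,B:1):1,(C:1,D:1):1) — the worked 4-tip example."""
    return phylo_vcv(tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def star5() -> PhyloCovariance:
    """Equal-depth star phylogeny: C proportional to the identity."""
    return phylo_vcv(tree_from_newick("(A:2,B:2,C:2,D:2,E:2);"))


CENSUS_HEADER = ("stem_id,plot_id,genus,species,growth_form,census_date,"
                 "diameter,pom_height,alive,method_tape,new_pom_diameter")
PLOT_HEADER = "plot_id,latitude,longitude,elevation,annual_precip,E,area"


def write_fixture_inputs(tmp_path, census_rows, plot_rows, wd_rows, newick):
    """Write the four input files from row strings; returns the path dict."""
    paths = {
        "census": tmp_path / "census.csv",
        "plots": tmp_path / "plots.csv",
        "wd": tmp_path / "wd.csv",
        "tree": tmp_path / "tree.nwk",
    }
    paths["census"].write_text("\n".join([CENSUS_HEADER, *census_rows]) + "\n")
    paths["plots"].write_text("\n".join([PLOT_HEADER, *plot_rows]) + "\n")
    paths["wd"].write_text("\n".join(["taxon,wd", *wd_rows]) + "\n")
    paths["tree"].write_text(newick + "\n")
    return paths


@pytest.fixture
def three_stem_inputs(tmp_path):
    """Hand-written 3-stem, 1-plot fixture on a 3-tip tree."""
    census = [
        "s1,p1,Inga,Inga edulis,tree,2000.0,20.0,1.3,True,True,",
        "s1,p1,Inga,Inga edulis,tree,2005.0,22.0,1.3,True,True,",
        "s2,p1,Protium,,tree,2000.0,15.0,1.3,True,True,",
        "s2,p1,Protium,,tree,2005.0,15.5,1.3,True,True,",
        "s3,p1,Euterpe,Euterpe precatoria,palm,2000.0,12.0,1.3,True,True,",
    ]
    plots = ["p1,-3.0,-60.0,100.0,2500.0,0.05,1.0"]
    wd = ["Inga edulis,0.55", "Protium sp1,0.61", "Euterpe precatoria,0.4"]
    return write_fixture_inputs(tmp_path, census, plots, wd, "((Inga:1,Protium:1):1,Euterpe:2);")
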
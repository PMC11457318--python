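"""Published resistance-gene landscape numbers for *P. cerasus* 'Schattenmorelle'.

These are the reported values for the two subgenomes of the sequenced sour
cherry cultivar: they parameterize the study-scale synthetic landscape and
feed the arithmetic consistency checks (completeness percentages, NB-LRR
phylogeny partition).  They are inputs, never outputs, of this package.
"""

from __future__ import annotations

from cherry_rga.classify import RGAClass

#: Transcripts carrying at least one canonical RGA domain, per subgenome.
TRANSCRIPTS_ANY_DOMAIN = {"A": 19_570, "F": 19_142}

#: Transcripts with a complete architecture (TNL/CNL/RNL/RLK/RLP), per subgenome.
TRANSCRIPTS_COMPLETE = {"A": 804, "F": 817}

#: Full-length genes per class per subgenome (A = avium-like, F = fruticosa-like).
GENE_COUNTS = {
    "A": {
        RGAClass.CNL: 103,
        RGAClass.RNL: 10,
        RGAClass.TNL: 69,
        RGAClass.LYSM: 20,
        RGAClass.RLK: 198,
        RGAClass.RLP: 114,
    },
    "F": {
        RGAClass.CNL: 111,
        RGAClass.RNL: 13,
        RGAClass.TNL: 74,
        RGAClass.LYSM: 21,
        RGAClass.RLK: 212,
        RGAClass.RLP: 112,
    },
}

#: NB-LRR transcripts in the phylogeny, by class.
TREE_CLASS_PARTITION = {RGAClass.RNL: 34, RGAClass.TNL: 266, RGAClass.CNL: 281}

#: Physical clusters (>= 2 genes) per subgenome.
CLUSTER_COUNTS = {"A": 16, "F": 18}

#: The chromosome carrying an RPW8-NB-LRR cluster in both subgenomes.
SHARED_RNL_CLUSTER_CHROMOSOME = "Chro7"
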
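"""Shared RDF namespaces.

QB is the W3C RDF Data Cube Vocabulary.  LMDS is the summary / access
policy vocabulary (endpoint URLs, cube membership, graph-level grants);
SEHR carries the clinical dimension and measure terms used by the
bundled example federation.  The LMDS and SEHR IRIs below are local
interpretations: only the term local names are significant.
"""

from rdflib import Namespace
from rdflib.namespace import RDF, XSD  # noqa: F401  (re-exported)

QB = Namespace("http://purl.org/linked-data/cube#")
LMDS = Namespace("http://example.org/lmds#")
SEHR = Namespace("http://example.org/sehr#")
EX = Namespace("http://example.org/l2s#")
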
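# Synthetic stand-in for the interconnected signalling-hub gene set
# (Tor-complex and MAP-kinase neighbourhood); one gene id per line.
hub001
hub002
hub003
hub004
hub005
hub006
hub007
hub008
hub009
hub010
hub011
hub012
hub013
hub014
hub015
hub016
hub017
hub018
hub019
hub020
hub021
hub022
hub023
hub024
hub025
hub026
hub027
hub028
hub029
hub030
hub031
hub032
hub033
hub034
hub035
hub036
hub037
hub038
hub039
hub040
hub041
hub042
hub043
hub044
hub045
hub046
hub047
hub048
hub049
hub050
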
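# Synthetic stand-in for the screen's 131 robust negative interactors
# (the real gene list is not redistributable here); 39 of the ids
# belong to the signalling-hub set in synthetic_hub_genes.txt.
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
neg001
neg002
neg003
neg004
neg005
neg006
neg007
neg008
neg009
neg010
neg011
neg012
neg013
neg014
neg015
neg016
neg017
neg018
neg019
neg020
neg021
neg022
neg023
neg024
neg025
neg026
neg027
neg028
neg029
neg030
neg031
neg032
neg033
neg034
neg035
neg036
neg037
neg038
neg039
neg040
neg041
neg042
neg043
neg044
neg045
neg046
neg047
neg048
neg049
neg050
neg051
neg052
neg053
neg054
neg055
neg056
neg057
neg058
neg059
neg060
neg061
neg062
neg063
neg064
neg065
neg066
neg067
neg068
neg069
neg070
neg071
neg072
neg073
neg074
neg075
neg076
neg077
neg078
neg079
neg080
neg081
neg082
neg083
neg084
neg085
neg086
neg087
neg088
neg089
neg090
neg091
neg092
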
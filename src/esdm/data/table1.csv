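species,total_observations,unique_observations,endemic
Anodonta impura,5,5,0
Utterbackia imbecillis,2,2,0
Actinonaias coyensis,43,23,1
Actinonaias medellina,17,10,0
Actinonaias signata,79,24,1
Disconaias disca,33,15,1
Disconaias fimbriata,67,28,0
Cyrtonaias tampicoensis,34,20,0
Friersonia iridella,134,43,1
Nephronaias aztecorum,21,13,0
Popenaias berezai,99,39,0
Popenaias semirasa,60,10,1
Psoronaias semigranosa,11,5,0
Megalonaias nickliniana,5,3,0
Anodontites cylindracea,11,10,0
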
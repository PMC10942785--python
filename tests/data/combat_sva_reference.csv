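"r0","r1","r2","r3","r4"
-1.13248228020305,-1.25056960783118,0.756621953596851,0.848350264359363,0.192998774653753
-0.441005206908212,0.183926195580735,-0.139568018660712,-0.0556562652369558,0.898512051340061
0.154765437347981,0.994011980960984,-0.076301997706389,0.315477500141123,0.102715582720358
-1.44518671347015,-0.624086677560538,-1.02412440915282,-1.08247005635567,-0.677242362109852
2.28887150725126,-1.33495485081923,1.15765720250557,-2.32208166083831,-0.938210694803855
0.679305240304892,0.634993265380529,0.724210578600185,0.624780672802592,-0.682592617361256
-0.153128624230632,1.05378835355139,-0.612014851141855,-1.84486460402889,-1.85883225701089
-0.724283587240466,0.517523652563526,-0.121398876814327,0.502997390965441,-0.818308666108813
0.464492313430063,0.45943509761553,0.443783452044157,0.779920408994945,-1.0439724443382
-0.207225851225683,-1.34375465385728,-0.881318214365256,0.80273504315485,-0.762753842431211
0.940082719893246,-0.1066323791127,1.41466531468492,0.770514625774092,-0.172863375919312
-0.370212392653706,-0.801433628994923,-1.5843953519965,-1.76542638962664,-1.73947956671758
-1.51835398314625,0.121535585134013,-0.413316972037659,-0.326579748297527,1.13691995747557
-0.359255046951361,0.619594347841739,-0.470318757868286,-0.104411913883525,-1.35492960383613
0.0774703835810396,0.677078031391359,-1.69507921701317,0.487125726028124,0.113717990234872
-0.145601574331743,-1.55062789288534,0.130850399589837,-0.860150358893909,0.0148769573237847
-0.105137148694299,1.34735540132886,-0.550765121902532,-1.00827276338823,-0.0729357372516848
0.0781423182639458,1.11985340240303,0.491608499059477,0.353323772803691,1.17406695258538
-1.3228595705926,-0.784977355336953,-1.2044160404427,-0.376735152573333,-1.67803028368285
0.543313890634501,-0.450078705766569,-1.75696915217122,-1.00949176089017,0.152590941855253
1.21325252162216,1.79354345224172,2.88983676156355,0.0753087956659291,-1.24402414399416
-1.68570060227178,0.136023591358604,-0.713044026375369,-0.739734685983281,-0.898652984745305
0.289442851279406,0.876484436098527,0.21445227241069,-0.493866691561084,-1.2420272183726
-1.67070994019592,-0.725579301244539,-0.393437480378806,1.72807505284623,0.023606771120373
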
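name,formula,conjugation_class,hydroxyl_class,parent,reference_rt_min,is_internal_standard,deuterium_count
CA,C24H40O5,unconjugated,tri,,15.6,0,0
ACA,C24H40O5,unconjugated,tri,,16.4,0,0
UCA,C24H40O5,unconjugated,tri,,12.8,0,0
alpha-MCA,C24H40O5,unconjugated,tri,,11.4,0,0
beta-MCA,C24H40O5,unconjugated,tri,,12.0,0,0
omega-MCA,C24H40O5,unconjugated,tri,,10.6,0,0
CDCA,C24H40O4,unconjugated,di,,23.3,0,0
DCA,C24H40O4,unconjugated,di,,24.3,0,0
UDCA,C24H40O4,unconjugated,di,,20.0,0,0
HDCA,C24H40O4,unconjugated,di,,19.0,0,0
IDCA,C24H40O4,unconjugated,di,,26.0,0,0
muro-CA,C24H40O4,unconjugated,di,,18.0,0,0
LCA,C24H40O3,unconjugated,mono,,34.5,0,0
ILCA,C24H40O3,unconjugated,mono,,31.5,0,0
AILCA,C24H40O3,unconjugated,mono,,33.0,0,0
APCA,C24H38O4,unconjugated,other,,27.6,0,0
7-keto-LCA,C24H38O4,unconjugated,other,,21.8,0,0
12-keto-LCA,C24H38O4,unconjugated,other,,24.6,0,0
7-keto-DCA,C24H38O5,unconjugated,other,,14.2,0,0
12-keto-DCA,C24H38O5,unconjugated,other,,16.6,0,0
3-DHCA,C24H38O5,unconjugated,other,,13.0,0,0
DHCA,C24H34O5,unconjugated,other,,8.8,0,0
DHLCA,C24H38O3,unconjugated,other,,29.0,0,0
di-oxo-LCA,C24H36O4,unconjugated,other,,21.0,0,0
6-7-diketo-LCA,C24H36O5,unconjugated,other,,17.4,0,0
NCA,C23H38O5,unconjugated,other,,13.5,0,0
NDCA,C23H38O4,unconjugated,other,,19.8,0,0
NUDCA,C23H38O4,unconjugated,other,,16.9,0,0
GCA,C26H43NO6,glycine,tri,CA,10.2,0,0
GCDCA,C26H43NO5,glycine,di,CDCA,16.0,0,0
GDCA,C26H43NO5,glycine,di,DCA,17.0,0,0
GUDCA,C26H43NO5,glycine,di,UDCA,9.9,0,0
GHDCA,C26H43NO5,glycine,di,HDCA,12.4,0,0
GHCA,C26H43NO6,glycine,tri,,7.2,0,0
GLCA,C26H43NO4,glycine,mono,LCA,27.8,0,0
GDHCA,C26H37NO6,glycine,other,DHCA,4.4,0,0
TCA,C26H45NO7S,taurine,tri,CA,9.0,0,0
TCDCA,C26H45NO6S,taurine,di,CDCA,13.2,0,0
TDCA,C26H45NO6S,taurine,di,DCA,14.1,0,0
TUDCA,C26H45NO6S,taurine,di,UDCA,7.6,0,0
THCA,C26H45NO7S,taurine,tri,,6.9,0,0
TLCA,C26H45NO5S,taurine,mono,LCA,24.4,0,0
TDHCA,C26H39NO7S,taurine,other,DHCA,3.2,0,0
alpha-TMCA,C26H45NO7S,taurine,tri,alpha-MCA,5.8,0,0
beta-TMCA,C26H45NO7S,taurine,tri,beta-MCA,6.2,0,0
omega-TMCA,C26H45NO7S,taurine,tri,omega-MCA,5.2,0,0
d4-GUDCA,C26H43NO5,glycine,di,GUDCA,9.9,1,4
d4-GCA,C26H43NO6,glycine,tri,GCA,10.2,1,4
d4-TUDCA,C26H45NO6S,taurine,di,TUDCA,7.6,1,4
d4-TCA,C26H45NO7S,taurine,tri,TCA,9.0,1,4
d4-CA,C24H40O5,unconjugated,tri,CA,15.6,1,4
d4-UDCA,C24H40O4,unconjugated,di,UDCA,20.0,1,4
d4-GCDCA,C26H43NO5,glycine,di,GCDCA,16.0,1,4
d4-GDCA,C26H43NO5,glycine,di,GDCA,17.0,1,4
d4-TCDCA,C26H45NO6S,taurine,di,TCDCA,13.2,1,4
d6-TDCA,C26H45NO6S,taurine,di,TDCA,14.1,1,6
d4-CDCA,C24H40O4,unconjugated,di,CDCA,23.3,1,4
d4-DCA,C24H40O4,unconjugated,di,DCA,24.3,1,4
d4-GLCA,C26H43NO4,glycine,mono,GLCA,27.8,1,4
d4-LCA,C24H40O3,unconjugated,mono,LCA,34.5,1,4
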
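pattern,label
bns/main/,Feature
bns/1239/updateItem/,Feature
bns/1230/updateItem/,Feature
bns/1228/updateItem/,Feature
bns/1241/updateItem/,Feature
journal/add/,Journal
journal/,Journal
journal/1537/delete/,Journal
apps/share,Supporter
content/9/53/238/,1
apps/40/i,1.0.1
content/9/53/92/,1.1.0
92-mind-balance-basics/#carousel11,1.1.0
92-mind-balance-basics/#content2,1.1.1
92-mind-balance-basics/#content3,1.1.2
92-mind-balance-basics/#content4,1.1.3
/content/9/53/98/,1.2.0
98-personal-stories/#carousel1,1.2.0
98-personal-stories/#carousel2,1.2.1
98-personal-stories/#carousel3,1.2.2
content/9/53/104/,1.3.0
apps/42/i,1.3.0
apps/41/i,1.3.1
104-activity/#subconcept2,1.3.1
apps/41/addItem,Exercise
104-activity/#subconcept3,1.3.2
apps/14/,Mindfulness
content/9/54/239/,2
apps/33/i,2.0.1
content/9/54/93/,2.1.0
apps/33/update,2.0.1
content/9/54/99/,2.2.0
content/27-tune-1/99-personal-stories/#carousel1,2.2.0
content/27-tune-1/99-personal-stories/#carousel2,2.2.1
content/27-tune-1/99-personal-stories/#carousel3,2.2.2
content/27-tune-1/99-personal-stories/#carousel4,2.2.3
content/27-tune-1/99-personal-stories/#carousel5,2.2.4
content/9/54/105/,2.3.0
apps/15/i,Exercise
apps/2/i,2.3.1
content/27-tune-1/105-activity/#subconcept1,2.3.0
93-getting-grips-mood/#subconcept2,2.1.1
93-getting-grips-mood/#subconcept3,2.1.2
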
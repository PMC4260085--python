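id,datetime,url,sequence_assignment,session_number
8,08/03/2012 12:47,,Home,4
8,08/03/2012 12:47,bns/main/,Feature,4
8,08/03/2012 12:47,bns/1239/updateItem/,Feature,4
8,08/03/2012 12:47,bns/1230/updateItem/,Feature,4
8,08/03/2012 12:47,bns/1230/updateItem/,Feature,4
8,08/03/2012 12:47,bns/1228/updateItem/,Feature,4
8,08/03/2012 12:47,bns/1241/updateItem/,Feature,4
8,08/03/2012 12:48,journal/add/,Journal,4
8,08/03/2012 12:48,journal/,Journal,4
8,08/03/2012 12:49,journal/1537/delete/,Journal,4
8,08/03/2012 16:41,,Home,4
8,08/03/2012 16:41,journal/,Journal,4
8,08/03/2012 16:47,journal/add/,Journal,4
8,08/03/2012 16:47,journal/,Journal,4
8,08/03/2012 16:47,apps/share,Supporter,4
8,08/03/2012 16:47,,Home,4
8,08/03/2012 17:18,content/9/53/238/,1,4
8,08/03/2012 17:18,apps/40/i,1.0.1,4
8,08/03/2012 17:18,content/9/53/92/,1.1.0,4
8,08/03/2012 17:18,92-mind-balance-basics/#carousel11,1.1.0,4
8,08/03/2012 17:18,92-mind-balance-basics/#content2,1.1.1,4
8,08/03/2012 17:18,92-mind-balance-basics/#content3,1.1.2,4
8,08/03/2012 17:18,92-mind-balance-basics/#content4,1.1.3,4
8,08/03/2012 17:18,/content/9/53/98/,1.2.0,4
8,08/03/2012 17:18,98-personal-stories/#carousel1,1.2.0,4
8,08/03/2012 17:18,98-personal-stories/#carousel2,1.2.1,4
8,08/03/2012 17:18,98-personal-stories/#carousel3,1.2.2,4
8,08/03/2012 17:18,content/9/53/104/,1.3.0,4
8,08/03/2012 17:18,apps/42/i,1.3.0,4
8,08/03/2012 17:18,apps/41/i,1.3.1,4
8,08/03/2012 17:18,104-activity/#subconcept2,1.3.1,4
8,08/03/2012 17:20,apps/41/addItem,Exercise,4
8,08/03/2012 17:20,104-activity/#subconcept3,1.3.2,4
8,08/03/2012 17:21,apps/14/,Mindfulness,4
8,08/03/2012 17:21,apps/42/i,1.3.0,4
8,08/03/2012 17:21,apps/41/i,1.3.1,4
8,08/03/2012 17:21,104-activity/#subconcept2,1.3.1,4
8,08/03/2012 17:22,content/9/54/239/,2,4
8,08/03/2012 17:22,apps/33/i,2.0.1,4
8,08/03/2012 17:24,content/9/54/93/,2.1.0,4
8,08/03/2012 17:24,apps/33/i,2.0.1,4
8,08/03/2012 17:25,apps/33/i,2.0.1,4
8,08/03/2012 17:27,apps/33/update,2.0.1,4
8,08/03/2012 17:27,content/9/54/93/,2.1.0,4
8,08/03/2012 17:27,content/9/54/99/,2.2.0,4
8,08/03/2012 17:27,content/27-tune-1/99-personal-stories/#carousel1,2.2.0,4
8,08/03/2012 17:30,content/27-tune-1/99-personal-stories/#carousel2,2.2.1,4
8,08/03/2012 17:30,content/27-tune-1/99-personal-stories/#carousel3,2.2.2,4
8,08/03/2012 17:30,content/27-tune-1/99-personal-stories/#carousel4,2.2.3,4
8,08/03/2012 17:31,content/27-tune-1/99-personal-stories/#carousel5,2.2.4,4
8,08/03/2012 17:31,content/9/54/105/,2.3.0,4
8,08/03/2012 17:31,content/9/54/105/,2.3.0,4
8,08/03/2012 17:31,apps/15/i,Exercise,4
8,08/03/2012 17:31,apps/2/i,2.3.1,4
8,08/03/2012 17:31,content/27-tune-1/105-activity/#subconcept1,2.3.0,4
8,08/03/2012 17:31,content/27-tune-1/99-personal-stories/#carousel1,2.2.0,4
8,08/03/2012 17:33,93-getting-grips-mood/#subconcept2,2.1.1,4
8,08/03/2012 17:35,93-getting-grips-mood/#subconcept3,2.1.2,4
8,08/03/2012 18:16,journal/add/,Journal,4
8,08/03/2012 18:16,apps/share,Supporter,4
8,08/03/2012 18:17,,Home,4
8,08/03/2012 18:46,,Home,4
8,08/03/2012 18:46,journal/,Journal,4
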
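activity_code,macrodomain,superdomain,met,posture,is_sleep
talk_sit,Social,Domestic/Social,1.3,sit_lie,False
visit_friends,Social,Domestic/Social,2.0,stand,False
clean_room,Chores/Work,Domestic/Social,3.0,ambulatory,False
cook,Chores/Work,Domestic/Social,2.0,stand,False
garden,Chores/Work,Domestic/Social,4.0,ambulatory,False
paid_work_light,Chores/Work,Domestic/Social,2.3,stand,False
car_ride,Passive Transport,Passive Transport,1.2,sit_lie,False
bus_train_ride,Passive Transport,Passive Transport,1.2,sit_lie,False
soccer_light,Sport,Physical Activity,4.0,ambulatory,False
soccer_medium,Sport,Physical Activity,6.0,ambulatory,False
soccer_hard,Sport,Physical Activity,8.0,ambulatory,False
swimming_medium,Sport,Physical Activity,6.0,ambulatory,False
playground_games,Play,Physical Activity,4.5,ambulatory,False
ball_play,Play,Physical Activity,5.0,ambulatory,False
walk_transport,Active Transport,Physical Activity,3.5,ambulatory,False
cycle_transport,Active Transport,Physical Activity,6.0,ambulatory,False
listen_music,Quiet Time,Quiet Time,1.2,sit_lie,False
chill_out,Quiet Time,Quiet Time,1.3,sit_lie,False
stand_around,Quiet Time,Quiet Time,1.4,stand,False
classroom_sitting,Classroom,School-related,1.5,sit_lie,False
classroom_standing,Classroom,School-related,1.8,stand,False
homework,Study/Homework/Music,School-related,1.4,sit_lie,False
play_instrument,Study/Homework/Music,School-related,2.0,sit_lie,False
read_book,Reading,School-related,1.3,sit_lie,False
watch_tv,TV,Screen Time,1.2,sit_lie,False
computer_use,Computer,Screen Time,1.5,sit_lie,False
videogames,Videogames,Screen Time,1.4,sit_lie,False
eat_meal,Eating,Self-care,1.4,sit_lie,False
snack,Eating,Self-care,1.4,sit_lie,False
shower_groom,Grooming,Self-care,2.0,stand,False
get_dressed,Grooming,Self-care,2.5,stand,False
sleep_night,Sleep,Sleep,0.9,sit_lie,True
nap,Sleep,Sleep,0.9,sit_lie,True
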